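"""MCMC convergence and model-fit diagnostics.

Every reported effect is gated on the Gelman-Rubin potential scale
reduction factor (split-chain R-hat < 1.1) and the effective number of
draws (n_eff > 10); model fit is screened with a posterior predictive
p-value (ppp), which should sit near 0.5 when replicated data resemble
the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RHAT_GATE = 1.1
NEFF_GATE = 10.0
PPP_BAND = (0.1, 0.9)  # default screening band around the ideal 0.5


class DiagnosticsError(ValueError):
    pass


def _split(chains: np.ndarray) -> np.ndarray:
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2:
        raise DiagnosticsError("need >= 2 chains")
    if n < 10:
        raise DiagnosticsError("need >= 10 draws per chain")
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)


def rhat(chains) -> float:
    """Split-chain Gelman-Rubin R-hat.

    Each chain is halved, then R-hat = sqrt(((n-1)/n W + B/n) / W)
    with W the mean within-chain variance and B the between-chain
    variance of the chain means.
    """
    sp = _split(chains)
    m, n = sp.shape
    means = sp.mean(axis=1)
    W = sp.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def effective_draws(chains) -> float:
    """Autocorrelation-corrected effective sample size.

    Combined-chain ESS: n_eff = m*n / (1 + 2 sum rho_t), with the lag
    correlations estimated from FFT autocovariances averaged across
    chains (using the between/within variance combination) and the sum
    truncated by Geyer's initial monotone positive sequence.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2:
        raise DiagnosticsError("need >= 2 chains")
    if n < 10:
        raise DiagnosticsError("need >= 10 draws per chain")

    centered = chains - chains.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)

    W = mean_acov[0] * n / (n - 1.0)
    var_plus = W * (n - 1.0) / n + chains.mean(axis=1).var(ddof=1)
    if var_plus == 0:
        return float(m * n)
    rho = 1.0 - (W - mean_acov) / var_plus

    # Geyer initial positive + monotone sequence on paired sums
    tmax = (n - 1) // 2
    pair = rho[1 : 2 * tmax + 1 : 2] + rho[2 : 2 * tmax + 1 : 2]
    s = 0.0
    prev = np.inf
    for p in pair:
        if p < 0:
            break
        p = min(p, prev)
        prev = p
        s += p
    ess = m * n / (1.0 + 2.0 * s)
    return float(min(ess, m * n))


def posterior_predictive_p(observed_stat: float, replicated_stats) -> float:
    """ppp = fraction of replicated statistics >= the observed one."""
    reps = np.asarray(replicated_stats, dtype=float)
    if reps.size == 0:
        raise DiagnosticsError("no replicated statistics")
    return float(np.mean(reps >= observed_stat))


@dataclass
class DiagnosticsReport:
    """Per-effect convergence diagnostics plus a model-level ppp."""

    rhat: dict[str, float]
    n_eff: dict[str, float]
    ppp: float | None = None
    ppp_band: tuple[float, float] = PPP_BAND

    @property
    def rhat_flags(self) -> dict[str, bool]:
        """True where the R-hat gate (>= 1.1) is violated."""
        return {k: v >= RHAT_GATE for k, v in self.rhat.items()}

    @property
    def neff_flags(self) -> dict[str, bool]:
        """True where the n_eff gate (<= 10) is violated."""
        return {k: v <= NEFF_GATE for k, v in self.n_eff.items()}

    @property
    def ppp_ok(self) -> bool | None:
        if self.ppp is None:
            return None
        lo, hi = self.ppp_band
        return lo < self.ppp < hi

    @property
    def all_ok(self) -> bool:
        ok = not any(self.rhat_flags.values()) and not any(self.neff_flags.values())
        if self.ppp is not None:
            ok = ok and bool(self.ppp_ok)
        return ok


def diagnose(post, names=None, ppp: float | None = None) -> DiagnosticsReport:
    """Build a DiagnosticsReport for the named effects of a
    PosteriorDraws (defaults to all)."""
    names = list(names) if names is not None else post.names()
    return DiagnosticsReport(
        rhat={n: rhat(post.chains(n)) for n in names},
        n_eff={n: effective_draws(post.chains(n)) for n in names},
        ppp=ppp,
    )
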