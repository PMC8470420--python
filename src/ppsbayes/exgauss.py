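"""Ex-Gaussian distribution primitives.

The ex-Gaussian — the convolution of a Normal(mu, sigma) with an
Exponential of mean tau — is the standard parametric family for simple
reaction times: the Gaussian part captures sensorimotor transmission,
the exponential tail captures decision/attention lapses.

Parameterisation: ``tau`` is the *mean* of the exponential component
(not its rate), so the distribution has mean ``mu + tau`` and variance
``sigma**2 + tau**2``.  All quantities are in seconds throughout the
package; conversion to milliseconds happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, log_ndtr


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian parameters (seconds).

    mu    -- mean of the Gaussian component
    sigma -- SD of the Gaussian component, > 0
    tau   -- mean of the exponential component, > 0
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2


def exgauss_logpdf(x, mu, sigma, tau):
    """Log-density of the ex-Gaussian, numerically stable.

    Two algebraically equivalent forms are combined by branch:

    * ``log f = -log(2 tau) - (x-mu)^2/(2 sigma^2) + log erfcx(y)`` with
      ``y = (sigma/tau - (x-mu)/sigma)/sqrt(2)`` — stable for ``y >= 0``
      (small tau / left tail), where the naive exponential overflows;
    * ``log f = -log tau + (mu-x)/tau + sigma^2/(2 tau^2)
      + log Phi((x-mu)/sigma - sigma/tau)`` via ``log_ndtr`` — stable
      for ``y < 0`` (deep exponential tail), where erfcx overflows.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, tau = (np.asarray(v, dtype=float) for v in (mu, sigma, tau))
    if np.any(sigma <= 0) or np.any(tau <= 0):
        raise ValueError("sigma and tau must be > 0")
    z = (x - mu) / sigma - sigma / tau
    y = -z / np.sqrt(2.0)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        left = (
            -np.log(2.0 * tau)
            - ((x - mu) ** 2) / (2.0 * sigma**2)
            + np.log(erfcx(y))
        )
        right = (
            -np.log(tau)
            + (mu - x) / tau
            + sigma**2 / (2.0 * tau**2)
            + log_ndtr(z)
        )
    return np.where(y >= 0.0, left, right)


def exgauss_pdf(x, params: ExGaussParams):
    """Density of the ex-Gaussian at ``x`` (scalar or array)."""
    return np.exp(exgauss_logpdf(x, params.mu, params.sigma, params.tau))


def exgauss_rng(params: ExGaussParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` ex-Gaussian samples, reproducible by ``seed``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(params.mu, params.sigma, size=n) + rng.exponential(
        params.tau, size=n
    )


def exgauss_loglik(data, params: ExGaussParams) -> float:
    """Sum of log-densities over ``data``.

    Returns ``-inf`` only through genuinely zero densities (log_ndtr
    underflows gracefully); empty data is an error.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("data must be non-empty")
    return float(
        np.sum(exgauss_logpdf(data, params.mu, params.sigma, params.tau))
    )


def moment_estimates(data) -> ExGaussParams:
    """Method-of-moments ex-Gaussian estimate (used to initialise MCMC).

    tau is recovered from the third central moment (tau^3 = m3/2),
    clipped so that sigma^2 = var - tau^2 stays positive.
    """
    data = np.asarray(data, dtype=float)
    m = data.mean()
    v = data.var()
    m3 = np.mean((data - m) ** 3)
    tau = np.cbrt(max(m3 / 2.0, 1e-12))
    tau = float(np.clip(tau, 0.05 * np.sqrt(v), 0.95 * np.sqrt(v)))
    sigma = float(np.sqrt(max(v - tau**2, 0.05 * v)))
    return ExGaussParams(mu=float(m - tau), sigma=sigma, tau=tau)
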