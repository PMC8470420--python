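"""MCMC engine: blocked Metropolis with an optional Hamiltonian block.

All models in this package are sampled with the same engine.  Scalar /
scale parameters are updated by adaptive random-walk Metropolis blocks;
high-dimensional, strongly correlated mean structures (regression
coefficients plus participant-level effects) can be updated by a
Hamiltonian Monte Carlo block with analytic gradients supplied by the
model.  Several independent chains are updated simultaneously through
vectorised evaluations: the log-posterior receives a ``(n_chains, dim)``
matrix and returns ``(n_chains,)``.

During warm-up each Metropolis block adapts (i) a per-chain scalar step
size by a Robbins-Monro recursion targeting a given acceptance rate and
(ii) a block proposal covariance estimated from the warm-up history;
the HMC block adapts its per-chain step size (target acceptance 0.8)
and a diagonal mass matrix.  Adaptation is frozen after warm-up, so the
retained draws come from a fixed-kernel Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class Block:
    """One random-walk update block: parameter indices and an initial
    proposal scale per coordinate (roughly the expected posterior SD).

    If ``direction`` is given, the block proposes 1-D moves along that
    fixed vector (over ``idx`` coordinates) instead of adapting a full
    covariance — useful for weakly identified ridges.

    If ``proposal`` is given, it is called as ``proposal(theta, rng,
    scale)`` with the per-chain adapted scalar ``scale`` and must return
    either a step ``(n_chains, len(idx))`` for a symmetric move, or a
    tuple ``(step, log_jacobian)`` for a bijective map family
    ``T_delta`` with ``delta`` drawn symmetrically (e.g. the scaling
    moves used to traverse hierarchical variance funnels); the log
    Jacobian enters the acceptance ratio.
    """

    name: str
    idx: np.ndarray
    init_scale: np.ndarray
    direction: np.ndarray | None = None
    proposal: Callable | None = None

    def __post_init__(self) -> None:
        self.idx = np.asarray(self.idx, dtype=np.int64)
        self.init_scale = np.broadcast_to(
            np.asarray(self.init_scale, dtype=float), self.idx.shape
        ).copy()
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)

    @property
    def structured(self) -> bool:
        return self.direction is not None or self.proposal is not None


@dataclass
class HamiltonianBlock:
    """Gradient-based update of a parameter subset.

    ``value_and_grad(theta)`` must return the full log-posterior
    ``(n_chains,)`` and its gradient ``(n_chains, len(idx))`` with
    respect to the ``idx`` coordinates, holding the rest fixed.
    """

    name: str
    idx: np.ndarray
    value_and_grad: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    init_scale: np.ndarray
    n_leapfrog: int = 12
    init_step: float = 0.2
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        self.idx = np.asarray(self.idx, dtype=np.int64)
        self.init_scale = np.broadcast_to(
            np.asarray(self.init_scale, dtype=float), self.idx.shape
        ).copy()


@dataclass
class PosteriorDraws:
    """Named posterior draws with chain structure.

    ``draws`` maps an effect name to a ``(n_chains, n_kept)`` array.
    ``scale`` records the measurement scale ("seconds" for RT models);
    unit conversion is a rendering concern, never applied here.
    """

    draws: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    scale: str = "seconds"

    def names(self) -> list[str]:
        return list(self.draws)

    def chains(self, name: str) -> np.ndarray:
        return self.draws[name]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def stacked(self, names: Sequence[str]) -> np.ndarray:
        """(n_terms, n_chains, n_kept) array for a list of effects."""
        return np.stack([self.draws[n] for n in names])


def _hmc_update(theta, lp, hb, inv_mass, log_eps, rng):
    """One vectorised HMC trajectory for all chains; returns updated
    (theta, lp, accept_mask).  Divergent trajectories produce
    non-finite energies and are rejected chainwise."""
    C = theta.shape[0]
    idx = hb.idx
    sd_p = 1.0 / np.sqrt(inv_mass)  # momentum SD per coordinate
    p = rng.standard_normal((C, idx.size)) * sd_p[None, :]
    kin0 = 0.5 * ((p**2) * inv_mass[None, :]).sum(axis=1)

    q = theta.copy()
    _, grad = hb.value_and_grad(q)
    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    eps = np.exp(log_eps)[:, None]
    # randomise trajectory length a little to avoid resonances
    L = max(1, int(hb.n_leapfrog * rng.uniform(0.8, 1.2)))
    p_half = p + 0.5 * eps * grad
    for step in range(L):
        q[:, idx] = q[:, idx] + eps * (p_half * inv_mass[None, :])
        lp_new, grad = hb.value_and_grad(q)
        if step < L - 1:
            p_half = p_half + eps * grad
    p_end = p_half + 0.5 * eps * grad
    kin1 = 0.5 * ((p_end**2) * inv_mass[None, :]).sum(axis=1)
    errstate.__exit__(None, None, None)

    lp_new = np.where(np.isfinite(lp_new), lp_new, -np.inf)
    log_alpha = (lp_new - kin1) - (lp - kin0)
    accept = np.log(rng.random(C)) < log_alpha
    theta[accept] = q[accept]
    lp = np.where(accept, lp_new, lp)
    return theta, lp, accept


def sample_posterior(
    log_post: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    blocks: Sequence[Block],
    *,
    hmc: HamiltonianBlock | None = None,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed=0,
    target_accept: float = 0.28,
    init_jitter: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the blocked sampler; returns ``(draws, info)`` where draws is
    ``(n_chains, n_iter - n_warmup, dim)`` (post-warm-up only) and info
    carries acceptance rates per block.

    ``init_jitter`` scales the per-block initial scales used to
    overdisperse the chain starting points.
    """
    if n_warmup >= n_iter:
        raise ValueError("n_warmup must be < n_iter")
    rng = np.random.default_rng(seed) if rng is None else rng
    init = np.asarray(init, dtype=float)
    dim = init.size

    jitter_blocks = list(blocks) + (
        [Block(hmc.name, hmc.idx, hmc.init_scale)] if hmc is not None else []
    )
    theta = np.tile(init, (n_chains, 1))
    for b in jitter_blocks:
        if b.structured:
            continue
        theta[:, b.idx] += init_jitter * b.init_scale * rng.standard_normal(
            (n_chains, b.idx.size)
        )
    lp = np.asarray(log_post(theta), dtype=float)
    if not np.all(np.isfinite(lp)):
        bad = ~np.isfinite(lp)
        theta[bad] = init
        lp = np.asarray(log_post(theta), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise RuntimeError("log-posterior not finite at the initial point")

    n_keep = n_iter - n_warmup
    kept = np.empty((n_chains, n_keep, dim))
    warm_hist = np.empty((n_chains, n_warmup, dim))

    # Metropolis block state
    log_scale = [
        np.full(n_chains, np.log(b.init_scale[0]))
        if b.structured
        else np.zeros(n_chains)
        for b in blocks
    ]
    chol = [np.diag(b.init_scale) for b in blocks]
    acc_count = [np.zeros(n_chains) for _ in blocks]
    adapt_t = [0 for _ in blocks]
    # HMC state
    if hmc is not None:
        inv_mass = 1.0 / hmc.init_scale**2
        hmc_log_eps = np.full(
            n_chains, np.log(hmc.init_step / np.sqrt(np.median(inv_mass)))
        )
        hmc_acc = np.zeros(n_chains)
        hmc_adapt_t = 0
    cov_update_at = (
        {n_warmup // 4, n_warmup // 2, 3 * n_warmup // 4}
        if n_warmup >= 200
        else set()
    )

    for t in range(n_iter):
        for bi, b in enumerate(blocks):
            log_jac = 0.0
            if b.proposal is not None:
                out = b.proposal(theta, rng, np.exp(log_scale[bi]))
                step, log_jac = out if isinstance(out, tuple) else (out, 0.0)
            elif b.direction is not None:
                eps = rng.standard_normal(n_chains)
                step = (np.exp(log_scale[bi]) * eps)[:, None] * b.direction[None, :]
            else:
                k = b.idx.size
                eps = rng.standard_normal((n_chains, k))
                step = np.exp(log_scale[bi])[:, None] * (eps @ chol[bi].T)
            prop = theta.copy()
            prop[:, b.idx] += step
            lp_prop = np.asarray(log_post(prop), dtype=float)
            lp_prop = np.where(np.isfinite(lp_prop), lp_prop, -np.inf)
            accept = np.log(rng.random(n_chains)) < (lp_prop - lp + log_jac)
            theta[accept] = prop[accept]
            lp = np.where(accept, lp_prop, lp)
            acc_count[bi] += accept
            if t < n_warmup:
                adapt_t[bi] += 1
                gain = 1.0 / max(adapt_t[bi], 10) ** 0.6
                log_scale[bi] += gain * (accept.astype(float) - target_accept)

        if hmc is not None:
            theta, lp, accept = _hmc_update(
                theta, lp, hmc, inv_mass, hmc_log_eps, rng
            )
            hmc_acc += accept
            if t < n_warmup:
                hmc_adapt_t += 1
                gain = 1.0 / max(hmc_adapt_t, 10) ** 0.6
                hmc_log_eps += gain * (accept.astype(float) - hmc.target_accept)

        if t < n_warmup:
            warm_hist[:, t] = theta
            if (t + 1) in cov_update_at:
                lo = max(0, t + 1 - 500)
                for bi, b in enumerate(blocks):
                    if b.structured:
                        continue
                    seg = warm_hist[:, lo : t + 1, b.idx].reshape(-1, b.idx.size)
                    cov = np.atleast_2d(np.cov(seg, rowvar=False))
                    cov += np.diag(np.maximum(np.diag(cov), 1e-12)) * 1e-6
                    cov += 1e-14 * np.eye(b.idx.size)
                    try:
                        chol[bi] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        chol[bi] = np.diag(np.sqrt(np.diag(cov)))
                    log_scale[bi][:] = np.log(2.38 / np.sqrt(b.idx.size))
                    adapt_t[bi] = 0
                if hmc is not None:
                    seg = warm_hist[:, lo : t + 1, hmc.idx]
                    var = seg.reshape(-1, hmc.idx.size).var(axis=0)
                    inv_mass = 1.0 / np.maximum(var, 1e-12)
                    hmc_adapt_t = 0
        else:
            kept[:, t - n_warmup] = theta

    info = {
        "accept_rate": {
            b.name: acc_count[bi] / n_iter for bi, b in enumerate(blocks)
        },
        "n_chains": n_chains,
        "n_iter": n_iter,
        "n_warmup": n_warmup,
    }
    if hmc is not None:
        info["accept_rate"][hmc.name] = hmc_acc / n_iter
    return kept, info
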