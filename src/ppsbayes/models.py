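"""Bayesian models: the hierarchical ex-Gaussian congruency-effect model
for the two RT tasks, cumulative ordinal models for clinical scales,
robust (Student-t) linear models for continuous variables, and the
covariate model relating per-participant Congruency Effects to clinical
predictors.

The congruency model is the centrepiece.  Raw reaction times are
ex-Gaussian distributed,

    rt_i ~ ExGaussian(mu_i, sigma, tau)
    mu_i = b0 + a_{p(i)} + c_i * CE_i
    CE_i = X_i beta + Z_i u_{p(i)}

where ``c_i`` is 1 on incongruent and 0 on congruent trials, so the
latent Congruency Effect CE is exactly the incongruent-minus-congruent
RT shift for the trial's design cell; X holds the 12 population-level
terms (Space/Background, Group, linear and quadratic Time, and their
interactions) and Z the participant-level varying intercept and
time/space slopes.  Effect priors are Normal(0, variance 5) on the
seconds scale; participant effects are non-centred with half-normal
scale hyperpriors; sigma and tau are shared across trials.

All models are sampled with the package's blocked adaptive Metropolis
engine (4 chains by default) and return named `PosteriorDraws`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr

from . import coding
from .coding import build_ce_design, nli_rank, population_terms, zscore
from .designs import ParticipantProfile
from .exgauss import exgauss_logpdf, moment_estimates
from .sampler import Block, HamiltonianBlock, PosteriorDraws, sample_posterior


class DataError(ValueError):
    pass


class DegenerateDataError(DataError):
    pass


EFFECT_PRIOR_VARIANCE = 5.0  # Normal(0, 5) prior on all population effects


# ---------------------------------------------------------------------------
# congruency-effect model
# ---------------------------------------------------------------------------


@dataclass
class CongruencyModelSpec:
    """Settings for the hierarchical ex-Gaussian congruency model."""

    factor: str = "space"  # "space" (visuo-tactile) or "background" (sidedness)
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    effect_prior_variance: float = EFFECT_PRIOR_VARIANCE
    hyper_scale: float = 1.0  # half-normal scale for SDs, sigma, tau (seconds)

    def __post_init__(self) -> None:
        if self.chains < 4:
            raise ValueError("at least 4 chains are required")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")


def _congruency_log_post(X, Z, c, pidx, rt, P, prior_var, hyper_scale):
    """Vectorised log-posterior over a (chains, dim) parameter matrix.

    Layout: [b0, beta(12), log_sigma, log_tau, log_sd_a, log_sd_u(4),
    a(P), z_u(P*4, participant-major)].  The participant RT intercepts
    ``a`` are centred (each participant's baseline is strongly
    identified by hundreds of trials); the participant CE effects are
    non-centred (prior-dominated, given their small scale).
    """
    n_beta = X.shape[1]
    iz = 1 + n_beta + 2 + 1 + 4
    rt_row = rt[None, :]
    c_row = c[None, :]
    onehot = np.zeros((rt.size, P))
    onehot[np.arange(rt.size), pidx] = 1.0

    def _unpack(theta):
        return (
            theta[:, 0],  # b0
            theta[:, 1 : 1 + n_beta],  # beta
            theta[:, 1 + n_beta],  # log_sigma
            theta[:, 2 + n_beta],  # log_tau
            theta[:, 3 + n_beta],  # log_sd_a
            theta[:, 4 + n_beta : 8 + n_beta],  # log_sd_u
            theta[:, iz : iz + P],  # a
            theta[:, iz + P :].reshape(theta.shape[0], P, 4),  # z_u
        )

    def _lp_parts(theta):
        # extreme proposals overflow harmlessly to -inf and are rejected
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _lp_parts_inner(theta)

    def _lp_parts_inner(theta):
        b0, beta, log_sigma, log_tau, log_sd_a, log_sd_u, a, z_u = _unpack(theta)
        sigma = np.exp(log_sigma)
        tau = np.exp(log_tau)
        sd_a = np.exp(log_sd_a)
        sd_u = np.exp(log_sd_u)
        u = sd_u[:, None, :] * z_u  # (C, P, 4)
        ce = beta @ X.T + np.einsum("nk,cnk->cn", Z, u[:, pidx, :])
        mu = b0[:, None] + a[:, pidx] + c_row * ce
        ll = exgauss_logpdf(rt_row, mu, sigma[:, None], tau[:, None]).sum(axis=1)
        lp = ll
        lp = lp - (b0**2 + (beta**2).sum(axis=1)) / (2 * prior_var)
        lp = lp - (a**2).sum(axis=1) / (2 * sd_a**2) - P * log_sd_a
        lp = lp - 0.5 * (z_u**2).sum(axis=(1, 2))
        for s, ls in ((sigma, log_sigma), (tau, log_tau), (sd_a, log_sd_a)):
            lp = lp - s**2 / (2 * hyper_scale**2) + ls
        lp = lp - (sd_u**2).sum(axis=1) / (2 * hyper_scale**2) + log_sd_u.sum(axis=1)
        return lp, mu, sigma, tau, sd_a, sd_u

    def log_post(theta: np.ndarray) -> np.ndarray:
        return _lp_parts(theta)[0]

    def value_and_grad(theta: np.ndarray):
        """Log-posterior and gradient w.r.t. the mean-structure
        coordinates [b0, beta, a, z_u] (scales held fixed)."""
        from scipy.special import log_ndtr

        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            b0, beta, _, _, log_sd_a, log_sd_u, a, z_u = _unpack(theta)
            lp, mu, sigma, tau, sd_a, sd_u = _lp_parts(theta)
            zq = (rt_row - mu) / sigma[:, None] - (sigma / tau)[:, None]
            # inverse Mills ratio phi(z)/Phi(z), stable in logs
            log_phi = -0.5 * zq**2 - 0.5 * np.log(2 * np.pi)
            mills = np.exp(log_phi - log_ndtr(zq))
            g = 1.0 / tau[:, None] - mills / sigma[:, None]  # d loglik/d mu_i
            gc = g * c_row
            grad_b0 = g.sum(axis=1) - b0 / prior_var
            grad_beta = gc @ X - beta / prior_var
            grad_a = g @ onehot - a / sd_a[:, None] ** 2
            gz = np.stack(
                [(gc * Z[None, :, k]) @ onehot for k in range(4)], axis=2
            )  # (C, P, 4): d loglik / d u(p, k)
            grad_zu = gz * sd_u[:, None, :] - z_u
            # hyper-scales (log parameterisation, half-normal priors)
            hs2 = hyper_scale**2
            grad_lsa = (
                (a**2).sum(axis=1) / sd_a**2 - P + 1.0 - sd_a**2 / hs2
            )
            grad_lsu = (
                (gz * (sd_u[:, None, :] * z_u)).sum(axis=1)
                + 1.0
                - sd_u**2 / hs2
            )
            C = theta.shape[0]
            grad = np.concatenate(
                [
                    grad_b0[:, None],
                    grad_beta,
                    grad_lsa[:, None],
                    grad_lsu,
                    grad_a,
                    grad_zu.reshape(C, 4 * P),
                ],
                axis=1,
            )
        return lp, grad

    log_post.value_and_grad = value_and_grad
    return log_post


def fit_congruency_model(
    trials: pd.DataFrame, spec: CongruencyModelSpec | None = None
) -> PosteriorDraws:
    """Fit the hierarchical ex-Gaussian congruency model by MCMC.

    ``trials`` is a trial table (one condition only for the
    visuo-tactile task); catch/false/error/timeout trials (no RT) are
    excluded.  Returns draws for the 12 population-level effects, the
    variance components and the residual parameters, all in seconds.
    """
    spec = spec or CongruencyModelSpec()
    X, Z, c, pidx, pids, rt = build_ce_design(trials, factor=spec.factor)
    if np.any(rt <= 0):
        raise DataError("non-positive RTs in input")
    P = len(pids)
    if P < 2:
        raise DataError("need >= 2 participants")
    frame = pd.DataFrame({"p": pidx, "c": c})
    levels = frame.groupby("p")["c"].nunique()
    if (levels < 2).any():
        raise DataError("every participant needs congruent and incongruent trials")

    mom = moment_estimates(rt)
    n_beta = X.shape[1]
    dim = 1 + n_beta + 2 + 1 + 4 + P + 4 * P
    init = np.zeros(dim)
    init[0] = mom.mu
    init[1 + n_beta] = np.log(mom.sigma)
    init[2 + n_beta] = np.log(mom.tau)
    init[3 + n_beta] = np.log(0.02)
    init[4 + n_beta : 8 + n_beta] = np.log(0.01)
    iz = 8 + n_beta
    part_mean = pd.Series(rt).groupby(pidx).mean().to_numpy()
    init[iz : iz + P] = part_mean - rt.mean()

    log_post = _congruency_log_post(
        X, Z, c, pidx, rt, P, spec.effect_prior_variance, spec.hyper_scale
    )

    # population effect <-> participant-effect ridges: shifting a beta and
    # compensating the (scaled) varying effects leaves the likelihood
    # invariant, so a joint move mixes these weakly identified directions.
    # (beta column, varying-effect component, participant weights)
    g_p = np.zeros(P)
    g_p[pidx] = X[:, 2]
    ones_p = np.ones(P)
    ridges = [
        (0, 0, ones_p), (2, 0, g_p),
        (3, 1, ones_p), (8, 1, g_p),
        (4, 2, ones_p), (9, 2, g_p),
        (1, 3, ones_p), (5, 3, g_p),
    ]
    ridge_idx = np.concatenate(
        [np.arange(1, 1 + n_beta), np.arange(iz + P, iz + 5 * P)]
    )

    def ridge_proposal(theta, rng, scale):
        C = theta.shape[0]
        delta = rng.standard_normal((C, len(ridges))) * 0.005 * scale[:, None]
        step = np.zeros((C, ridge_idx.size))
        for m, (j, k, w) in enumerate(ridges):
            sd_uk = np.exp(theta[:, 4 + n_beta + k])
            step[:, j] += delta[:, m]
            step[:, n_beta + 4 * np.arange(P) + k] -= (
                delta[:, m][:, None] * w[None, :] / sd_uk[:, None]
            )
        return step

    recenter_idx = np.concatenate([[0], np.arange(iz, iz + P)])

    # scaling moves through the hierarchical variance funnels, one per
    # variance component so each step size can adapt separately:
    # log_sd_a up with a rescaled (keeps a/sd_a, so the prior term is
    # invariant); log_sd_u up with z_u shrunk (keeps u = sd_u * z_u, so
    # the likelihood is invariant); both need a Jacobian correction.
    def make_funnel_a():
        idx = np.concatenate([[3 + n_beta], np.arange(iz, iz + P)])

        def proposal(theta, rng, scale):
            C = theta.shape[0]
            d = rng.standard_normal(C) * scale
            step = np.zeros((C, idx.size))
            step[:, 0] = d
            a = theta[:, iz : iz + P]
            step[:, 1:] = a * np.expm1(d)[:, None]
            return step, P * d

        return Block("funnel_a", idx, 0.15, proposal=proposal)

    def make_funnel_u(k):
        zk = iz + P + 4 * np.arange(P) + k
        idx = np.concatenate([[4 + n_beta + k], zk])

        def proposal(theta, rng, scale):
            C = theta.shape[0]
            d = rng.standard_normal(C) * scale
            step = np.zeros((C, idx.size))
            step[:, 0] = d
            z = theta[:, zk]
            step[:, 1:] = z * np.expm1(-d)[:, None]
            return step, -P * d

        return Block(f"funnel_u{k}", idx, 0.25, proposal=proposal)

    blocks = [
        Block("resid", np.array([1 + n_beta, 2 + n_beta]), 0.03),
        Block("hyper", np.arange(3 + n_beta, 8 + n_beta), 0.3),
        Block(
            "recenter",
            recenter_idx,
            0.008,
            direction=np.concatenate([[1.0], -np.ones(P)]),
        ),
        Block("ridge", ridge_idx, 1.0, proposal=ridge_proposal),
        make_funnel_a(),
    ] + [make_funnel_u(k) for k in range(4)]
    # mean structure [b0, beta, log-SD hyperparameters, a, z_u] moves by
    # Hamiltonian updates — random-walk proposals mix too slowly along
    # the intercept ridges and through the variance funnels
    mean_idx = np.concatenate(
        [
            np.arange(0, 1 + n_beta),
            np.arange(3 + n_beta, 8 + n_beta),
            np.arange(iz, iz + 5 * P),
        ]
    )
    mean_scale = np.concatenate(
        [
            [0.01],
            np.full(n_beta, 0.005),
            np.full(5, 0.25),
            np.full(P, 0.01),
            np.full(4 * P, 0.8),
        ]
    )
    hmc = HamiltonianBlock(
        "mean", mean_idx, log_post.value_and_grad, mean_scale, n_leapfrog=12
    )
    draws, info = sample_posterior(
        log_post,
        init,
        blocks,
        hmc=hmc,
        n_chains=spec.chains,
        n_iter=spec.iterations,
        n_warmup=spec.warmup,
        seed=spec.seed,
    )

    factor_label = "Space" if spec.factor == "space" else "Background"
    terms = population_terms(factor_label)
    named: dict[str, np.ndarray] = {"rt_baseline": draws[:, :, 0]}
    for j, t in enumerate(terms):
        named[t] = draws[:, :, 1 + j]
    named["sigma"] = np.exp(draws[:, :, 1 + n_beta])
    named["tau"] = np.exp(draws[:, :, 2 + n_beta])
    named["sd_participant_rt"] = np.exp(draws[:, :, 3 + n_beta])
    for k, lab in enumerate(("ce_intercept", "ce_time", "ce_time2",
                             f"ce_{spec.factor}")):
        named[f"sd_{lab}"] = np.exp(draws[:, :, 4 + n_beta + k])

    meta = {
        **info,
        "terms": terms,
        "factor": spec.factor,
        "participants": pids,
        "seed": spec.seed,
        "n_trials": int(rt.size),
        "raw_draws": draws,
        "design": {"X": X, "Z": Z, "c": c, "pidx": pidx, "rt": rt},
    }
    return PosteriorDraws(draws=named, meta=meta, scale="seconds")


def congruency_ppp(
    post: PosteriorDraws, n_rep: int = 200, seed=0, stat="mean"
) -> float:
    """Posterior predictive p-value for a fitted congruency model.

    Replicates the full trial set from ``n_rep`` random posterior draws
    and compares a discrepancy statistic (grand mean RT by default,
    ``"var"`` for the variance-based alternative) between observed and
    replicated data.
    """
    from .diagnostics import posterior_predictive_p

    rng = np.random.default_rng(seed)
    d = post.meta["design"]
    raw = post.meta["raw_draws"]
    n_beta = len(post.meta["terms"])
    P = len(post.meta["participants"])
    iz = 8 + n_beta
    X, Z, c, pidx, rt = d["X"], d["Z"], d["c"], d["pidx"], d["rt"]
    stat_fn = np.var if stat == "var" else np.mean
    C, K, _ = raw.shape
    reps = np.empty(n_rep)
    for r in range(n_rep):
        th = raw[rng.integers(C), rng.integers(K)][None, :]
        b0 = th[:, 0]
        beta = th[:, 1 : 1 + n_beta]
        sigma = np.exp(th[0, 1 + n_beta])
        tau = np.exp(th[0, 2 + n_beta])
        sd_u = np.exp(th[:, 4 + n_beta : 8 + n_beta])
        a = th[:, iz : iz + P]
        z_u = th[:, iz + P :].reshape(1, P, 4)
        u = sd_u[:, None, :] * z_u
        ce = beta @ X.T + np.einsum("nk,cnk->cn", Z, u[:, pidx, :])
        mu = (b0[:, None] + a[:, pidx] + c[None, :] * ce)[0]
        sim = rng.normal(mu, sigma) + rng.exponential(tau, size=mu.size)
        reps[r] = stat_fn(sim)
    return posterior_predictive_p(stat_fn(rt), reps)


# ---------------------------------------------------------------------------
# ordinal cumulative model
# ---------------------------------------------------------------------------


@dataclass
class OrdinalModelSpec:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    effect_prior_variance: float = EFFECT_PRIOR_VARIANCE

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def fit_ordinal_model(
    scores,
    X: np.ndarray,
    spec: OrdinalModelSpec | None = None,
    term_names: Sequence[str] | None = None,
) -> PosteriorDraws:
    """Cumulative-link (logit) ordinal regression by MCMC.

    P(y <= k) = logistic(c_k - eta), eta = X beta, with strictly
    increasing thresholds (parameterised as first threshold plus log
    spacings) and Normal(0, variance 5) effect priors.  ``X`` should use
    sum-to-zero factor codes and contain no intercept column (the
    thresholds absorb it).  Returns draws for each term and threshold.
    """
    spec = spec or OrdinalModelSpec()
    y = np.asarray(scores)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise DataError("X rows must match number of scores")
    cats = np.unique(y)
    K = cats.size
    if K < 2:
        raise DegenerateDataError("ordinal outcome has a single category")
    ycode = np.searchsorted(cats, y)
    p = X.shape[1]
    term_names = list(term_names) if term_names else [f"b{j}" for j in range(p)]

    # empirical-CDF-based threshold starting values
    cum = np.cumsum(np.bincount(ycode, minlength=K))[:-1] / y.size
    cum = np.clip(cum, 0.02, 0.98)
    c0 = np.log(cum / (1 - cum))
    c0 = np.maximum.accumulate(c0 + 1e-3 * np.arange(K - 1))

    prior_var = spec.effect_prior_variance

    def log_post(theta):
        beta = theta[:, :p]
        c1 = theta[:, p]
        if K > 2:
            deltas = np.exp(theta[:, p + 1 :])
            cuts = np.concatenate(
                [c1[:, None], c1[:, None] + np.cumsum(deltas, axis=1)], axis=1
            )
        else:
            cuts = c1[:, None]
        eta = beta @ X.T  # (C, N)
        padded = np.concatenate(
            [np.full((cuts.shape[0], 1), -np.inf), cuts,
             np.full((cuts.shape[0], 1), np.inf)],
            axis=1,
        )
        upper = padded[:, ycode + 1] - eta
        lower = padded[:, ycode] - eta
        prob = _expit(upper) - _expit(lower)
        ll = np.log(np.clip(prob, 1e-300, None)).sum(axis=1)
        lp = ll - (beta**2).sum(axis=1) / (2 * prior_var)
        lp = lp - cuts[:, 0] ** 2 / (2 * prior_var)
        if K > 2:
            lp = lp - 0.5 * (theta[:, p + 1 :] ** 2).sum(axis=1) / 1.5**2
        return lp

    dim = p + (K - 1)
    init = np.zeros(dim)
    init[p] = c0[0]
    if K > 2:
        init[p + 1 :] = np.log(np.maximum(np.diff(c0), 0.05))
    blocks = [
        Block("beta", np.arange(p), 0.2),
        Block("cuts", np.arange(p, dim), 0.2),
    ]
    draws, info = sample_posterior(
        log_post, init, blocks,
        n_chains=spec.chains, n_iter=spec.iterations, n_warmup=spec.warmup,
        seed=spec.seed,
    )
    named = {t: draws[:, :, j] for j, t in enumerate(term_names)}
    c1 = draws[:, :, p]
    cuts = [c1]
    for j in range(K - 2):
        cuts.append(cuts[-1] + np.exp(draws[:, :, p + 1 + j]))
    for k, ck in enumerate(cuts, start=1):
        named[f"threshold_{k}"] = ck
    meta = {**info, "terms": term_names, "categories": cats.tolist(),
            "seed": spec.seed}
    return PosteriorDraws(draws=named, meta=meta, scale="latent-logit")


# ---------------------------------------------------------------------------
# robust linear model
# ---------------------------------------------------------------------------


@dataclass
class RobustLinearSpec:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    effect_prior_variance: float = EFFECT_PRIOR_VARIANCE
    student_t: bool = True  # False -> Gaussian likelihood (comparison fits)


def _student_t_logpdf(x, nu, loc, scale):
    z = (x - loc) / scale
    return (
        gammaln((nu + 1) / 2)
        - gammaln(nu / 2)
        - 0.5 * np.log(nu * np.pi)
        - np.log(scale)
        - (nu + 1) / 2 * np.log1p(z**2 / nu)
    )


def fit_robust_linear(
    values,
    X: np.ndarray,
    spec: RobustLinearSpec | None = None,
    term_names: Sequence[str] | None = None,
) -> PosteriorDraws:
    """Robust Bayesian linear model: y ~ Student-t(nu, X beta, s).

    The degrees of freedom nu > 1 get a weak exponential prior
    (nu - 1 ~ Exp(mean 29)), so the likelihood can approach a Gaussian
    when the data carry no outliers but stays heavy-tailed otherwise.
    ``X`` should include an explicit intercept column.
    """
    spec = spec or RobustLinearSpec()
    y = np.asarray(values, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise DataError("X rows must match number of values")
    if np.std(y) == 0:
        raise DegenerateDataError("zero variance in response")
    p = X.shape[1]
    term_names = list(term_names) if term_names else [f"b{j}" for j in range(p)]
    sd_y = y.std(ddof=1)
    prior_var = spec.effect_prior_variance
    s_scale = 2.0 * sd_y  # half-normal scale for the residual SD

    # precondition the coefficients by their approximate Gaussian
    # posterior covariance: with n close to p the design can be near
    # collinear and some combinations are prior-dominated (SD sqrt(5))
    # while others are data-pinned — a spread no diagonal mass matrix
    # covers.  Sampling runs in whitened coordinates beta = L b.
    ls_beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = max(y.size - rank, 1)
    s0 = float(np.sqrt(rss[0] / dof)) if rss.size else sd_y
    s0 = max(s0, 0.1 * sd_y)
    precision = X.T @ X / s0**2 + np.eye(p) / prior_var
    L = np.linalg.cholesky(np.linalg.inv(precision))

    def log_post(theta):
        beta = theta[:, :p] @ L.T
        s = np.exp(theta[:, p])
        eta = beta @ X.T
        resid = y[None, :] - eta
        if spec.student_t:
            nu = 1.0 + np.exp(theta[:, p + 1])
            ll = _student_t_logpdf(
                resid, nu[:, None], 0.0, s[:, None]
            ).sum(axis=1)
            lp_nu = -(nu - 1.0) / 29.0 + theta[:, p + 1]
        else:
            ll = (-0.5 * (resid / s[:, None]) ** 2
                  - np.log(s[:, None]) - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            lp_nu = 0.0
        lp = ll - (beta**2).sum(axis=1) / (2 * prior_var)
        lp = lp - s**2 / (2 * s_scale**2) + theta[:, p]
        return lp + lp_nu

    def value_and_grad(theta):
        """Log-posterior and gradient over the (whitened) coefficient
        block, which moves by Hamiltonian updates."""
        beta = theta[:, :p] @ L.T
        s = np.exp(theta[:, p])
        resid = y[None, :] - beta @ X.T
        z = resid / s[:, None]
        if spec.student_t:
            nu = (1.0 + np.exp(theta[:, p + 1]))[:, None]
            dldeta = (nu + 1.0) * z / (s[:, None] * (nu + z**2))
        else:
            dldeta = z / s[:, None]
        grad = (dldeta @ X - beta / prior_var) @ L
        return log_post(theta), grad

    dim = p + (2 if spec.student_t else 1)
    init = np.zeros(dim)
    init[:p] = np.linalg.solve(L, ls_beta)
    init[p] = np.log(sd_y)
    if spec.student_t:
        init[p + 1] = np.log(20.0)
    blocks = [Block("scale", np.arange(p, dim), 0.2)]
    hmc = HamiltonianBlock(
        "beta", np.arange(p), value_and_grad, np.ones(p), n_leapfrog=10,
    )
    draws, info = sample_posterior(
        log_post, init, blocks, hmc=hmc,
        n_chains=spec.chains, n_iter=spec.iterations, n_warmup=spec.warmup,
        seed=spec.seed,
    )
    draws[:, :, :p] = draws[:, :, :p] @ L.T  # back to coefficient scale
    named = {t: draws[:, :, j] for j, t in enumerate(term_names)}
    named["residual_scale"] = np.exp(draws[:, :, p])
    if spec.student_t:
        named["nu"] = 1.0 + np.exp(draws[:, :, p + 1])
    meta = {**info, "terms": term_names, "seed": spec.seed}
    return PosteriorDraws(draws=named, meta=meta, scale="response")


# ---------------------------------------------------------------------------
# covariate model (clinical predictors of the T1 congruency effect)
# ---------------------------------------------------------------------------

COVARIATE_TERMS = [
    "Intercept",
    "Group",
    "NLI",
    "Lesion Onset",
    "PSFS-Frequency",
    "PSFS-Intensity",
    "VMIQ2",
    "Group:NLI",
    "Group:Lesion Onset",
    "Group:PSFS-Frequency",
    "Group:PSFS-Intensity",
    "Group:VMIQ2",
]


@dataclass
class CovariateModelSpec:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    effect_prior_variance: float = EFFECT_PRIOR_VARIANCE


def covariate_design(profiles: Sequence[ParticipantProfile]) -> np.ndarray:
    """12-term design: intercept, Group, five z-scored clinical
    covariates (NLI rank, lesion onset, PSFS frequency/intensity,
    VMIQ-2 average) and the Group x covariate interactions."""
    cols = {}
    try:
        cols["NLI"] = np.array([nli_rank(p.nli_label) for p in profiles], float)
        cols["Lesion Onset"] = np.array([p.lesion_onset_years for p in profiles])
        cols["PSFS-Frequency"] = np.array(
            [float(p.psfs_frequency) for p in profiles]
        )
        cols["PSFS-Intensity"] = np.array(
            [float(p.psfs_intensity) for p in profiles]
        )
        cols["VMIQ2"] = np.array([float(p.vmiq2_avg) for p in profiles])
    except TypeError as exc:
        raise DataError("missing clinical covariate on a profile") from exc
    g = np.array([coding.GROUP_CODE[p.group] for p in profiles])
    Xc = [np.ones(len(profiles)), g]
    for name in ("NLI", "Lesion Onset", "PSFS-Frequency", "PSFS-Intensity", "VMIQ2"):
        Xc.append(zscore(cols[name]))
    for j in range(2, 7):
        Xc.append(g * Xc[j])
    return np.column_stack(Xc)


def fit_covariate_model(
    responses,
    profiles: Sequence[ParticipantProfile],
    spec: CovariateModelSpec | None = None,
) -> PosteriorDraws:
    """Regress one response summary per participant (the T1 Congruency
    Effect of the cell of interest) on the clinical covariates."""
    spec = spec or CovariateModelSpec()
    responses = np.asarray(responses, dtype=float)
    if responses.size != len(profiles):
        raise DataError("one response per participant required")
    X = covariate_design(profiles)
    rl = RobustLinearSpec(
        chains=spec.chains, iterations=spec.iterations, warmup=spec.warmup,
        seed=spec.seed, effect_prior_variance=spec.effect_prior_variance,
    )
    post = fit_robust_linear(responses, X, rl, term_names=COVARIATE_TERMS)
    post.scale = "seconds"  # responses are congruency effects in seconds
    return post


def participant_ce_summary(
    trials: pd.DataFrame,
    *,
    timepoint: str = "T1",
    condition: str | None = "REAL",
    cell: tuple[str, str] = ("space", "homolateral"),
) -> pd.Series:
    """Empirical per-participant Congruency Effect (seconds): mean
    incongruent minus mean congruent RT in the selected cell."""
    t = trials
    if condition is not None and "condition" in t:
        t = t[t["condition"] == condition]
    t = t[t["timepoint"] == timepoint]
    col, level = cell
    t = t[(t[col] == level) & t["rt"].notna()]
    if t.empty:
        raise DataError("no trials in the requested cell")
    means = t.groupby(["participant_id", "congruency"])["rt"].mean().unstack()
    return means["incongruent"] - means["congruent"]
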