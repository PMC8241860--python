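"""Posterior predictive checks, PSIS-LOO predictive accuracy and the non-sigmoid flag.

Three complementary model-criticism tools:

* posterior predictive bands (50%/95%) with the fraction of observed points
  they contain — a well-specified model should cover ~50%/~95%;
* PSIS-LOO: leave-one-out expected log predictive density estimated by
  Pareto-smoothed importance sampling over posterior draws.  For the
  semi-parametric family the observations are correlated, so the pointwise
  predictive term is the exact multivariate-normal leave-one-out conditional
  density p(y_i | y_{-i}, theta), not the marginal;
* Delta-R^2: the extra variance explained by the semi-parametric mean curve
  over the sigmoid one (both from condition-specific M1 fits); proteins with
  Delta-R^2 >= 0.05 are flagged as deviating from sigmoid behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import ProteinMeltingData
from .models import curve_draws
from .sampling import ModelFit

_LOG_2PI = float(np.log(2.0 * np.pi))

PARETO_K_WARN = 0.7
NON_SIGMOID_THRESHOLD = 0.05


@dataclass
class PPCResult:
    """Posterior predictive replicate summaries for one protein/model."""

    T: np.ndarray
    y_obs: np.ndarray
    y_rep: np.ndarray                      # (R, n)
    intervals: dict[float, tuple[np.ndarray, np.ndarray]]
    coverage: dict[float, float]


def posterior_predictive_draws(fit: ModelFit, protein: ProteinMeltingData,
                               n_rep: int = 500, seed: int = 0,
                               levels=(0.5, 0.95)) -> PPCResult:
    """Draw replicated datasets from the posterior predictive distribution.

    Each replicate samples theta from the posterior and then y_rep from the
    observation model — N(S, sigma^2 I) for the sigmoid family and
    N(S, C + sigma^2 I) for the semi-parametric family.  Returns pointwise
    central predictive intervals and the fraction of observed points inside
    each.
    """
    rng = np.random.default_rng(seed)
    reps, y_obs_parts, T_parts = [], [], []
    for block, samples in zip(fit.blocks, fit.samples):
        S_draws = samples.n_draws
        idx = rng.integers(0, S_draws, size=n_rep)
        theta = samples.draws[idx]
        from .sigmoid import sigmoid_batch

        S = sigmoid_batch(block.T, theta[:, 0], theta[:, 1], theta[:, 2])
        if fit.spec.family == "sigmoid":
            y_rep = S + rng.normal(0.0, theta[:, 3][:, None], size=S.shape)
        else:
            Ts = block.T / block.T_scale
            d2 = (Ts[:, None] - Ts[None, :]) ** 2
            v, l, sg = theta[:, 4], theta[:, 5], theta[:, 3]
            K = v[:, None, None] ** 2 * np.exp(-d2[None] / (2.0 * l[:, None, None] ** 2))
            n = block.n_obs
            K[:, np.arange(n), np.arange(n)] += sg[:, None]**2 + 1e-12
            L = np.linalg.cholesky(K)
            z = rng.standard_normal((n_rep, n))
            y_rep = S + np.einsum("rij,rj->ri", L, z)
        reps.append(y_rep)
        y_obs_parts.append(block.y)
        T_parts.append(block.T)
    y_rep = np.hstack(reps)
    y_obs = np.concatenate(y_obs_parts)
    T = np.concatenate(T_parts)
    intervals, coverage = {}, {}
    for lev in levels:
        alpha = (1.0 - lev) / 2.0
        lo = np.quantile(y_rep, alpha, axis=0)
        hi = np.quantile(y_rep, 1.0 - alpha, axis=0)
        intervals[lev] = (lo, hi)
        coverage[lev] = float(np.mean((y_obs >= lo) & (y_obs <= hi)))
    return PPCResult(T=T, y_obs=y_obs, y_rep=y_rep, intervals=intervals,
                     coverage=coverage)


def pointwise_loglik(fit: ModelFit, max_draws: int = 1000) -> np.ndarray:
    """(S, n) matrix of pointwise log predictive terms log p(y_i | theta_s, .).

    Sigmoid family: independent normal densities.  Semi-parametric family:
    exact leave-one-out conditional normal densities of the correlated
    Gaussian, computed from the precision matrix per draw.
    """
    from .sigmoid import sigmoid_batch

    cols = []
    for block, samples in zip(fit.blocks, fit.samples):
        step = max(1, samples.n_draws // max_draws)
        theta = samples.draws[::step]
        S = sigmoid_batch(block.T, theta[:, 0], theta[:, 1], theta[:, 2])
        r = block.y[None, :] - S
        if fit.spec.family == "sigmoid":
            sg = theta[:, 3][:, None]
            ll = -0.5 * (r / sg) ** 2 - np.log(sg) - 0.5 * _LOG_2PI
        else:
            Ts = block.T / block.T_scale
            d2 = (Ts[:, None] - Ts[None, :]) ** 2
            v, l, sg = theta[:, 4], theta[:, 5], theta[:, 3]
            n = block.n_obs
            K = v[:, None, None] ** 2 * np.exp(-d2[None] / (2.0 * l[:, None, None] ** 2))
            K[:, np.arange(n), np.arange(n)] += sg[:, None]**2
            Q = np.linalg.inv(K)
            Qr = np.einsum("sij,sj->si", Q, r)
            Qd = np.diagonal(Q, axis1=1, axis2=2)
            # p(y_i | y_{-i}, theta): mean y_i - (Qr)_i/Q_ii, variance 1/Q_ii
            ll = 0.5 * np.log(Qd) - 0.5 * _LOG_2PI - 0.5 * Qr**2 / Qd
        cols.append(ll)
    S_min = min(c.shape[0] for c in cols)
    return np.hstack([c[:S_min] for c in cols])


@dataclass
class LooResult:
    elpd_loo: float
    se_elpd: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_high_k: int


def psis_loo_elpd(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO expected log pointwise predictive density from an (S, n) matrix.

    Importance ratios 1/p(y_i|theta_s) are stabilized by a generalized-Pareto
    fit to their largest 20% (arviz's PSIS); observations with Pareto
    k-hat > 0.7 are counted as unreliable.  Degenerate columns (identical
    draws, zero-variance ratios) fall back to the plain log density and are
    flagged with k-hat = inf.
    """
    import arviz as az

    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be a (draws, observations) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood entries")
    S, n = ll.shape
    pointwise = np.empty(n)
    ks = np.empty(n)
    spread = ll.max(axis=0) - ll.min(axis=0)
    degenerate = spread < 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll.T)  # samples on the last axis
    lw = np.asarray(lw)
    k = np.atleast_1d(np.asarray(k))
    for i in range(n):
        if degenerate[i]:
            pointwise[i] = ll[0, i]
            ks[i] = np.inf
        else:
            pointwise[i] = logsumexp(lw[i] + ll[:, i])
            ks[i] = k[i]
    elpd = float(np.sum(pointwise))
    se = float(np.sqrt(n * np.var(pointwise)))
    return LooResult(elpd_loo=elpd, se_elpd=se, pointwise=pointwise,
                     pareto_k=ks, n_high_k=int(np.sum(ks > PARETO_K_WARN)))


def variance_explained(protein: ProteinMeltingData,
                       fitted_curve_per_condition: dict[str, np.ndarray]) -> float:
    """R^2 of per-condition fitted curves, pooled over conditions and replicates.

    RSS uses the supplied (posterior-median) curve evaluated on the
    protein's temperature grid; TSS is taken around each condition's own
    mean, so R^2 = 0 for a flat fit at the condition mean.
    """
    rss, tss = 0.0, 0.0
    for cond in protein.conditions:
        curve = np.asarray(fitted_curve_per_condition[cond], dtype=float)
        _, y = protein.condition_block(cond)
        y = y.reshape(-1, protein.n_temperatures)
        rss += float(np.sum((y - curve[None, :]) ** 2))
        tss += float(np.sum((y - np.mean(y)) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares")
    return 1.0 - rss / tss


def median_fitted_curves(fit: ModelFit, protein: ProteinMeltingData,
                         max_draws: int = 400) -> dict[str, np.ndarray]:
    """Posterior-median fitted curve per condition on the protein's grid."""
    out = {}
    for cond in protein.conditions:
        if fit.spec.hypothesis == "M0":
            block, samples = fit.blocks[0], fit.samples[0]
        else:
            idx = list(protein.conditions).index(cond)
            block, samples = fit.blocks[idx], fit.samples[idx]
        step = max(1, samples.n_draws // max_draws)
        curves = curve_draws(samples.draws[::step], block, fit.spec.family,
                             protein.temperatures)
        out[cond] = np.median(curves, axis=0)
    return out


def delta_r2(protein: ProteinMeltingData, fit_sigmoid_m1: ModelFit,
             fit_semiparametric_m1: ModelFit) -> tuple[float, float, float]:
    """(R^2 semi-parametric, R^2 sigmoid, difference) from the two M1 fits."""
    r2_sig = variance_explained(protein, median_fitted_curves(fit_sigmoid_m1, protein))
    r2_semi = variance_explained(protein, median_fitted_curves(fit_semiparametric_m1, protein))
    return r2_semi, r2_sig, r2_semi - r2_sig


def flag_non_sigmoid(delta_r2_value: float,
                     threshold: float = NON_SIGMOID_THRESHOLD) -> bool:
    """True when the semi-parametric fit explains at least ``threshold`` more variance."""
    if not np.isfinite(delta_r2_value):
        raise ValueError("delta_r2 must be finite")
    return bool(delta_r2_value >= threshold)
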