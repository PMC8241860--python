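"""Posterior densities for the four melting-curve model variants.

Families: ``sigmoid`` (parameters a, b, p, sigma per block) and
``semiparametric`` (adds the GP hyperparameters v, l).  Hypotheses: ``M0``
(one parameter block fitted to both conditions pooled — under the
semi-parametric family the GP deviation is then shared across conditions)
and ``M1`` (condition-specific blocks).  Because conditions are a priori
independent under M1, its joint posterior factorizes and each condition is
fitted separately; `log_posterior` on the concatenated parameter vector is
the sum of the block posteriors.

Sampling runs on an unconstrained scale (log for positive parameters, logit
for the plateau) with the change-of-variables Jacobian included, so the
recorded log posterior is directly usable by the Laplace-Metropolis evidence
estimator.

The GP kernel operates on temperatures standardized by the SD of the
protein's temperature grid, which makes the length-scale dimensionless; its
log-normal prior (median ~0.6 grid-SDs, about 5 °C on the standard 37-67 °C
ladder) then discourages both data-interpolating and effectively constant
deviation functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from . import gp, priors as priors_mod
from .data import ProteinMeltingData
from .priors import PriorSpec, log_pdf, grad_log_pdf
from .sigmoid import sigmoid, sigmoid_batch, sigmoid_partials

_LOG_2PI = float(np.log(2.0 * np.pi))

FAMILIES = ("sigmoid", "semiparametric")
HYPOTHESES = ("M0", "M1")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "sigmoid": ("a", "b", "p", "sigma"),
    "semiparametric": ("a", "b", "p", "sigma", "v", "l"),
}

_DEFAULT_PRIORS = {
    "sigmoid": priors_mod.DEFAULT_SIGMOID_PRIORS,
    "semiparametric": priors_mod.DEFAULT_SEMIPARAMETRIC_PRIORS,
}


@dataclass(frozen=True)
class ModelSpec:
    """One model variant: family x hypothesis plus a prior per parameter."""

    family: str
    hypothesis: str
    priors: Mapping[str, PriorSpec] | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        pri = dict(self.priors) if self.priors is not None else dict(_DEFAULT_PRIORS[self.family])
        missing = [n for n in PARAM_NAMES[self.family] if n not in pri]
        if missing:
            raise ValueError(f"priors missing for parameters {missing}")
        object.__setattr__(self, "priors", pri)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family]

    @property
    def n_params_per_block(self) -> int:
        return len(self.param_names)

    @property
    def n_blocks(self) -> int:
        return 1 if self.hypothesis == "M0" else 2

    @property
    def n_params(self) -> int:
        return self.n_blocks * self.n_params_per_block


@dataclass
class DataBlock:
    """One fitted unit: concatenated observations sharing one parameter set.

    When the block is R identical copies of one temperature grid (the normal
    replicated design), the likelihood is evaluated through an exact
    decomposition of K = J_R (x) C + sigma^2 I into a D-dimensional Gaussian
    on the replicate mean (covariance R C + sigma^2 I) plus (R-1) D
    independent N(0, sigma^2) contrasts, which cuts the per-walker Cholesky
    from (RD)^3 to D^3 operations.
    """

    name: str
    y: np.ndarray
    T: np.ndarray
    T_scale: float
    d2_scaled: np.ndarray = field(init=False)
    grid: np.ndarray = field(init=False)
    n_rep: int = field(init=False)
    replicated: bool = field(init=False)
    d2_grid: np.ndarray = field(init=False)
    y_mean: np.ndarray = field(init=False)
    sum_y: np.ndarray = field(init=False)
    sum_y2: float = field(init=False)
    rss_contrasts: float = field(init=False)

    def __post_init__(self):
        Ts = self.T / self.T_scale
        self.d2_scaled = (Ts[:, None] - Ts[None, :]) ** 2
        # detect the replicated-grid structure
        D = 0
        for j in range(1, self.T.size + 1):
            if self.T.size % j == 0 and np.array_equal(
                    self.T, np.tile(self.T[:j], self.T.size // j)):
                D = j
                break
        self.grid = self.T[:D]
        self.n_rep = self.T.size // D
        self.replicated = True
        g = self.grid / self.T_scale
        self.d2_grid = (g[:, None] - g[None, :]) ** 2
        Y = self.y.reshape(self.n_rep, D)
        self.y_mean = Y.mean(axis=0)
        self.sum_y = Y.sum(axis=0)
        self.sum_y2 = float(np.sum(Y**2))
        # sum of squares orthogonal to the replicate mean
        self.rss_contrasts = float(self.sum_y2 - self.n_rep * np.sum(self.y_mean**2))

    @property
    def n_obs(self) -> int:
        return int(self.y.size)


def temperature_scale(protein: ProteinMeltingData) -> float:
    """SD of the temperature grid, used to standardize GP inputs."""
    return float(np.std(protein.temperatures))


def build_blocks(spec: ModelSpec, protein: ProteinMeltingData) -> list[DataBlock]:
    scale = temperature_scale(protein)
    if spec.hypothesis == "M0":
        T, y = protein.pooled_block()
        return [DataBlock("pooled", y, T, scale)]
    blocks = []
    for cond in protein.conditions:
        T, y = protein.condition_block(cond)
        blocks.append(DataBlock(cond, y, T, scale))
    return blocks


# ---------------------------------------------------------------------------
# transforms between constrained and unconstrained scales

def to_unconstrained(theta: np.ndarray, param_names: tuple[str, ...]) -> np.ndarray:
    x = np.empty_like(np.asarray(theta, dtype=float))
    for i, name in enumerate(param_names * (len(theta) // len(param_names))):
        if name == "p":
            x[i] = np.log(theta[i]) - np.log1p(-theta[i])
        else:
            x[i] = np.log(theta[i])
    return x


def to_constrained(x: np.ndarray, param_names: tuple[str, ...]) -> np.ndarray:
    theta = np.empty_like(np.asarray(x, dtype=float))
    for i, name in enumerate(param_names * (len(x) // len(param_names))):
        theta[i] = expit(x[i]) if name == "p" else np.exp(x[i])
    return theta


def to_constrained_batch(X: np.ndarray, param_names: tuple[str, ...]) -> np.ndarray:
    theta = np.empty_like(X)
    for i, name in enumerate(param_names):
        theta[:, i] = expit(X[:, i]) if name == "p" else np.exp(np.clip(X[:, i], -300, 300))
    return theta


# ---------------------------------------------------------------------------
# block posteriors

def _block_loglik(theta: dict[str, float], block: DataBlock, family: str) -> float:
    S = sigmoid(block.T, theta["a"], theta["b"], theta["p"])
    if family == "sigmoid":
        r = block.y - S
        n = block.n_obs
        return float(-0.5 * np.sum(r**2) / theta["sigma"] ** 2
                     - n * np.log(theta["sigma"]) - 0.5 * n * _LOG_2PI)
    return gp.gp_marginal_loglik(block.y, S, block.T / block.T_scale,
                                 theta["v"], theta["l"], theta["sigma"])


def block_log_posterior(x: np.ndarray, block: DataBlock, family: str,
                        priors: Mapping[str, PriorSpec]) -> float:
    names = PARAM_NAMES[family]
    theta_vec = to_constrained(np.asarray(x, dtype=float), names)
    theta = dict(zip(names, theta_vec))
    lp = 0.0
    for i, name in enumerate(names):
        lp += float(log_pdf(priors[name], theta_vec[i]))
        if name == "p":
            lp += np.log(theta_vec[i]) + np.log1p(-theta_vec[i])
        else:
            lp += x[i]
    if not np.isfinite(lp):
        return -np.inf
    try:
        ll = _block_loglik(theta, block, family)
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf
    return lp + ll if np.isfinite(ll) else -np.inf


def block_log_posterior_and_grad(x: np.ndarray, block: DataBlock, family: str,
                                 priors: Mapping[str, PriorSpec]):
    """(log posterior, gradient) on the unconstrained scale (analytic)."""
    names = PARAM_NAMES[family]
    x = np.asarray(x, dtype=float)
    theta_vec = to_constrained(x, names)
    p_val = theta_vec[names.index("p")]
    if p_val >= 1.0 or p_val <= 0.0 or not np.all(np.isfinite(theta_vec)):
        return -np.inf, np.zeros_like(x)   # float-saturated transform
    theta = dict(zip(names, theta_vec))
    # d theta / d x and d log|J| / d x per coordinate
    dtheta_dx = np.array([theta_vec[i] * (1 - theta_vec[i]) if n == "p" else theta_vec[i]
                          for i, n in enumerate(names)])
    djac_dx = np.array([1.0 - 2.0 * theta_vec[i] if n == "p" else 1.0
                        for i, n in enumerate(names)])
    lp = 0.0
    dprior_dtheta = np.zeros(len(names))
    for i, name in enumerate(names):
        lp += float(log_pdf(priors[name], theta_vec[i]))
        dprior_dtheta[i] = float(grad_log_pdf(priors[name], theta_vec[i]))
        lp += (np.log(theta_vec[i]) + np.log1p(-theta_vec[i])) if name == "p" else x[i]
    a, b, p, sg = theta["a"], theta["b"], theta["p"], theta["sigma"]
    S = sigmoid(block.T, a, b, p)
    dSda, dSdb, dSdp = sigmoid_partials(block.T, a, b, p)
    dll_dtheta = np.zeros(len(names))
    if family == "sigmoid":
        r = block.y - S
        n = block.n_obs
        ll = float(-0.5 * np.sum(r**2) / sg**2 - n * np.log(sg) - 0.5 * n * _LOG_2PI)
        w = r / sg**2
        dll_dtheta[0] = float(w @ dSda)
        dll_dtheta[1] = float(w @ dSdb)
        dll_dtheta[2] = float(w @ dSdp)
        dll_dtheta[3] = float(-n / sg + np.sum(r**2) / sg**3)
    else:
        v, l = theta["v"], theta["l"]
        ll, alpha, dv, dl, ds = gp.gp_marginal_loglik_grad(
            block.y, S, block.T / block.T_scale, v, l, sg)
        dll_dtheta[0] = float(alpha @ dSda)
        dll_dtheta[1] = float(alpha @ dSdb)
        dll_dtheta[2] = float(alpha @ dSdp)
        dll_dtheta[3] = ds
        dll_dtheta[4] = dv
        dll_dtheta[5] = dl
    grad = (dprior_dtheta + dll_dtheta) * dtheta_dx + djac_dx
    return lp + ll, grad


def block_log_posterior_batch(X: np.ndarray, block: DataBlock, family: str,
                              priors: Mapping[str, PriorSpec],
                              gp_backend: str = "dense") -> np.ndarray:
    """Vectorized log posterior over walkers; shape (W, P) -> (W,).

    ``gp_backend`` selects the dense marginal likelihood (exact, default) or
    the reduced-rank Hilbert-space approximation for the semi-parametric
    family.
    """
    names = PARAM_NAMES[family]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    theta = to_constrained_batch(X, names)
    lp = np.zeros(X.shape[0])
    with np.errstate(divide="ignore"):
        for i, name in enumerate(names):
            lp += log_pdf(priors[name], theta[:, i])
            if name == "p":
                lp += np.log(theta[:, i]) + np.log1p(-theta[:, i])
            else:
                lp += X[:, i]
    S = sigmoid_batch(block.grid, theta[:, 0], theta[:, 1], theta[:, 2])
    sg = theta[:, 3]
    n, R, D = block.n_obs, block.n_rep, block.grid.size
    # rss against the grid curve from sufficient statistics
    rss = block.sum_y2 + np.sum(R * S**2 - 2.0 * S * block.sum_y[None, :], axis=1)
    if family == "sigmoid":
        ll = -0.5 * rss / sg**2 - n * np.log(sg) - 0.5 * n * _LOG_2PI
    else:
        # replicate-mean component: N(sqrt(R) y_mean; sqrt(R) S, R C + sigma^2 I)
        z1 = np.sqrt(R) * block.y_mean
        m1 = np.sqrt(R) * S
        if gp_backend == "reduced_rank":
            ll = gp.reduced_rank_loglik_batch(z1, m1, block.grid / block.T_scale,
                                              np.sqrt(R) * theta[:, 4],
                                              theta[:, 5], sg)
        else:
            ll = gp.gp_marginal_loglik_batch(z1, m1, block.d2_grid,
                                             np.sqrt(R) * theta[:, 4], theta[:, 5], sg)
        if R > 1:
            ll = ll + (-0.5 * block.rss_contrasts / sg**2
                       - (n - D) * np.log(sg) - 0.5 * (n - D) * _LOG_2PI)
    out = lp + ll
    out[~np.isfinite(out)] = -np.inf
    return out


def log_posterior(spec: ModelSpec, protein: ProteinMeltingData, x: np.ndarray):
    """(log posterior, gradient) for the full parameter vector of ``spec``.

    Under M1 the vector concatenates the two condition blocks; the posterior
    is the sum of the independent block posteriors.
    """
    blocks = build_blocks(spec, protein)
    P = spec.n_params_per_block
    x = np.asarray(x, dtype=float)
    if x.size != spec.n_params:
        raise ValueError(f"expected {spec.n_params} parameters, got {x.size}")
    total, grads = 0.0, []
    for i, block in enumerate(blocks):
        val, g = block_log_posterior_and_grad(x[i * P:(i + 1) * P], block,
                                              spec.family, spec.priors)
        total += val
        grads.append(g)
    return total, np.concatenate(grads)


def curve_draws(theta_draws: np.ndarray, block: DataBlock, family: str,
                T_grid: np.ndarray) -> np.ndarray:
    """Per-draw inferred mean curve on ``T_grid``; shape (S, len(T_grid)).

    For the sigmoid family this is S_theta(T); for the semi-parametric
    family the posterior (conditional) mean of the GP deviation is added.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    a, b, p = theta_draws[:, 0], theta_draws[:, 1], theta_draws[:, 2]
    curves = sigmoid_batch(T_grid, a, b, p)
    if family == "semiparametric":
        S_at_data = sigmoid_batch(block.T, a, b, p)
        mu = gp.gp_conditional_mean_batch(
            block.y, S_at_data, block.T / block.T_scale,
            theta_draws[:, 4], theta_draws[:, 5], theta_draws[:, 3],
            T_grid / block.T_scale)
        curves = curves + mu
    return curves
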