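"""Three-parameter sigmoid melting model, least-squares fits and the NPARC baseline.

The melting curve is modelled as

    S_{a,b,p}(T) = (1 - p) / (1 + exp(b - a/T)) + p ,

a decreasing sigmoid in temperature T (°C) with lower plateau ``p`` and
shape parameters ``a, b > 0``; the midpoint (where S = (1+p)/2) sits at
T = a/b.  NPARC compares a shared-curve null fit (M0, both conditions
pooled) against condition-specific fits (M1) through an F statistic whose
null distribution is calibrated with *effective* degrees of freedom
estimated from the bulk of the per-protein statistics, because TPP residuals
are neither independent nor homoscedastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .data import ProteinMeltingData, TPPDataset


@dataclass(frozen=True)
class SigmoidParams:
    a: float
    b: float
    p: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and 0 < self.p < 1):
            raise ValueError(f"invalid sigmoid parameters {self}")


def sigmoid(T, a: float, b: float, p: float):
    """Evaluate S_{a,b,p}(T); requires T > 0."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("sigmoid requires T > 0")
    with np.errstate(over="ignore"):  # exp overflow saturates to the plateau
        return (1.0 - p) / (1.0 + np.exp(b - a / T)) + p


def sigmoid_batch(T: np.ndarray, a: np.ndarray, b: np.ndarray, p: np.ndarray) -> np.ndarray:
    """S(T) for a batch of parameter vectors: returns shape (len(a), len(T))."""
    z = b[:, None] - a[:, None] / T[None, :]
    z = np.clip(z, -700.0, 700.0)
    return (1.0 - p[:, None]) / (1.0 + np.exp(z)) + p[:, None]


def sigmoid_partials(T: np.ndarray, a: float, b: float, p: float):
    """(dS/da, dS/db, dS/dp) at each T."""
    z = np.clip(b - a / T, -350.0, 350.0)
    E = np.exp(z)
    denom2 = (1.0 + E) ** 2
    dSda = (1.0 - p) * E / denom2 / T
    dSdb = -(1.0 - p) * E / denom2
    dSdp = E / (1.0 + E)
    return dSda, dSdb, dSdp


# Multi-start box for the least-squares fits; the objective is multimodal in
# (a, b) so each fit is repeated from a coarse grid of starts.
_BOUNDS = (np.array([10.0, 0.5, 0.0]), np.array([5000.0, 100.0, 1.0 - 1e-9]))
_START_A = (300.0, 550.0, 900.0)
_START_B = (6.0, 11.0, 18.0)
_START_P = (0.05,)


@dataclass
class LSFit:
    """A least-squares sigmoid fit of one parameter block."""

    params: dict[str, SigmoidParams]
    rss: float
    residuals: dict[str, np.ndarray]
    converged: bool
    n_obs: int
    n_params: int


def _fit_block(T: np.ndarray, y: np.ndarray, extra_starts=()) -> tuple[SigmoidParams | None, float, np.ndarray]:
    best = None
    starts = [np.array([a0, b0, p0]) for a0 in _START_A for b0 in _START_B for p0 in _START_P]
    starts += [np.asarray(s, dtype=float) for s in extra_starts]

    def resid(theta):
        return sigmoid(T, *theta) - y

    for x0 in starts:
        x0 = np.clip(x0, _BOUNDS[0] + 1e-9, _BOUNDS[1] - 1e-9)
        try:
            sol = optimize.least_squares(resid, x0, bounds=_BOUNDS, method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.x[2] >= 1.0 or sol.x[2] < 0:
            continue
        if best is None or rss < best[1]:
            p_hat = min(max(sol.x[2], 1e-12), 1 - 1e-12)
            best = (SigmoidParams(sol.x[0], sol.x[1], p_hat), rss, sol.fun.copy())
    if best is None:
        return None, np.inf, np.full_like(y, np.nan)
    return best


def fit_sigmoid_ls(protein: ProteinMeltingData, model: str = "M0") -> LSFit:
    """Multi-start least-squares fit of the sigmoid under M0 (pooled) or M1.

    Under M1 each condition gets its own parameters; the M0 solution is
    reused as an additional start so that rss(M1) <= rss(M0) whenever M0
    converged.  Non-convergence is reported through ``converged=False``
    (flagged, excluded downstream), never an exception.
    """
    if model not in ("M0", "M1"):
        raise ValueError(f"model must be M0 or M1, got {model!r}")
    if model == "M0":
        T, y = protein.pooled_block()
        params, rss, res = _fit_block(T, y)
        ok = params is not None
        return LSFit(
            params={"pooled": params} if ok else {},
            rss=rss,
            residuals={"pooled": res},
            converged=ok,
            n_obs=y.size,
            n_params=3,
        )
    m0 = fit_sigmoid_ls(protein, "M0")
    extra = []
    if m0.converged:
        q = m0.params["pooled"]
        extra = [np.array([q.a, q.b, q.p])]
    params, residuals, rss, n_obs, ok = {}, {}, 0.0, 0, True
    for cond in protein.conditions:
        T, y = protein.condition_block(cond)
        pr, r, res = _fit_block(T, y, extra_starts=extra)
        if pr is None:
            ok = False
        else:
            params[cond] = pr
        residuals[cond] = res
        rss += r
        n_obs += y.size
    return LSFit(params=params, rss=rss if ok else np.inf, residuals=residuals,
                 converged=ok, n_obs=n_obs, n_params=6)


def nparc_f_statistic(rss0: float, rss1: float, d1: float, d2: float) -> float:
    """F = (d2/d1) * (RSS0 - RSS1) / RSS1."""
    if rss1 <= 0:
        raise ValueError("rss1 must be > 0 (degenerate perfect fit)")
    if d1 <= 0 or d2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return (d2 / d1) * (rss0 - rss1) / rss1


def nparc_f_for_protein(protein: ProteinMeltingData) -> tuple[float, float, float]:
    """(F, d1, d2) with counting dofs d1 = 3, d2 = n - 6 for one protein."""
    fit0 = fit_sigmoid_ls(protein, "M0")
    fit1 = fit_sigmoid_ls(protein, "M1")
    if not (fit0.converged and fit1.converged):
        return np.nan, np.nan, np.nan
    d1 = fit1.n_params - fit0.n_params
    d2 = fit1.n_obs - fit1.n_params
    rss1 = max(fit1.rss, 1e-300)
    return nparc_f_statistic(max(fit0.rss, fit1.rss), rss1, d1, d2), d1, d2


def estimate_effective_dof(F_values, trim_upper: float = 0.0,
                           min_count: int = 100) -> tuple[float, float]:
    """Effective (d1, d2) of a central-F null fitted to the bulk of the statistics.

    Maximum likelihood of the F(d1, d2) density over the statistics below
    the (1 - trim_upper) empirical quantile, with the density renormalized
    for the truncation.  With ``trim_upper > 0`` treatment-affected proteins
    in the upper tail do not distort the null (the pipeline trims 5% by
    default); d2 is identified mostly by the tail, so trimming inflates its
    variance and the untrimmed fit is preferred on clean data.
    """
    F = np.asarray(F_values, dtype=float)
    F = F[np.isfinite(F) & (F >= 0)]
    if F.size < min_count:
        raise ValueError(f"need at least {min_count} finite F statistics, got {F.size}")
    if np.allclose(F, F[0]):
        raise ValueError("all F statistics identical; cannot fit a null")
    if not 0 <= trim_upper < 0.5:
        raise ValueError("trim_upper must be in [0, 0.5)")
    if trim_upper > 0:
        cut = float(np.quantile(F, 1.0 - trim_upper))
        Ft = F[F <= cut]
    else:
        cut, Ft = np.inf, F
    Ft = np.clip(Ft, 1e-300, None)

    def nll(x):
        if np.any(np.abs(x) > 12.0):        # keep the search in a sane dof range
            return 1e12
        d1, d2 = np.exp(x)
        ll = stats.f.logpdf(Ft, d1, d2).sum()
        if np.isfinite(cut):
            ll -= Ft.size * stats.f.logcdf(cut, d1, d2)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for x0 in ([np.log(3.0), np.log(20.0)], [np.log(1.5), np.log(8.0)], [np.log(8.0), np.log(60.0)]):
        sol = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if np.isfinite(sol.fun) and sol.fun < 1e11 and (best is None or sol.fun < best.fun):
            best = sol
    if best is None:
        raise ValueError("effective-dof likelihood optimization failed")
    d1, d2 = np.exp(best.x)
    return float(d1), float(d2)


def nparc_pvalues(F_values, d1_eff: float, d2_eff: float) -> tuple[np.ndarray, np.ndarray]:
    """Right-tail p-values against F(d1_eff, d2_eff) and BH-adjusted values.

    Non-finite statistics (flagged fits) propagate as NaN in both outputs.
    """
    F = np.asarray(F_values, dtype=float)
    p = np.full(F.shape, np.nan)
    ok = np.isfinite(F)
    p[ok] = stats.f.sf(F[ok], d1_eff, d2_eff)
    p_adj = np.full(F.shape, np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return p, p_adj


def residual_correlation_matrix(dataset: TPPDataset,
                                fits: dict[str, LSFit] | None = None) -> np.ndarray:
    """D x D Spearman correlation of sigmoid-fit residuals across proteins.

    For each protein the per-condition (M1) residuals are averaged over
    replicates and conditions, giving one residual per temperature per
    protein; entry (j, j') is the Spearman correlation over proteins between
    temperatures T_j and T_j'.  Strong off-diagonal structure indicates that
    the independent-residual assumption of the sigmoid model fails.
    """
    D = dataset.temperatures.size
    rows = []
    for pid in dataset.complete_proteins():
        prot = dataset.proteins[pid]
        fit = fits.get(pid) if fits is not None else fit_sigmoid_ls(prot, "M1")
        if fit is None or not fit.converged:
            continue
        per_T = np.zeros(D)
        count = 0
        for cond in prot.conditions:
            res = fit.residuals[cond].reshape(-1, D)
            per_T += res.mean(axis=0)
            count += 1
        rows.append(per_T / count)
    if len(rows) < 3:
        raise ValueError("need residuals from at least 3 proteins")
    R = np.vstack(rows)
    corr = stats.spearmanr(R).statistic
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr
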