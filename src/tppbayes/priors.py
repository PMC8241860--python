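"""Log-density kernels for the prior families of the melting-curve models.

Five families are supported: gamma (shape/rate), beta, folded normal
(location/scale), folded Student-t (df/location/scale) and log-normal
(log-mean/log-sd).  Densities are implemented directly in numpy so that the
vectorized samplers can evaluate thousands of points per call without
`scipy.stats` dispatch overhead; unit tests cross-check every family against
scipy at random support points.

Conventions (documented because the literature is ambiguous):

* The second gamma parameter is a RATE, so ``gamma(7, 0.01)`` has mean 700 —
  the scale of the sigmoid shape parameter ``a``.
* The folded-normal/folded-t scale parameters are standard-deviation-like.
* Out-of-support evaluations return ``-inf`` rather than raising, so
  samplers can treat them as rejections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

FAMILIES = ("gamma", "beta", "folded_normal", "folded_student_t", "log_normal")

_LOG_2PI = float(np.log(2.0 * np.pi))


class PriorError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """One prior: a family name plus its named parameters."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise PriorError(f"unknown family {self.family!r}")
        p = self.params
        ok = {
            "gamma": len(p) == 2 and p[0] > 0 and p[1] > 0,
            "beta": len(p) == 2 and p[0] > 0 and p[1] > 0,
            "folded_normal": len(p) == 2 and p[1] > 0,
            "folded_student_t": len(p) == 3 and p[0] > 0 and p[2] > 0,
            "log_normal": len(p) == 2 and p[1] > 0,
        }[self.family]
        if not ok:
            raise PriorError(f"invalid parameters {p} for family {self.family!r}")


def gamma_prior(shape: float, rate: float) -> PriorSpec:
    return PriorSpec("gamma", (shape, rate))


def beta_prior(alpha: float, beta: float) -> PriorSpec:
    return PriorSpec("beta", (alpha, beta))


def folded_normal_prior(loc: float, scale: float) -> PriorSpec:
    return PriorSpec("folded_normal", (loc, scale))


def folded_student_t_prior(df: float, loc: float, scale: float) -> PriorSpec:
    return PriorSpec("folded_student_t", (df, loc, scale))


def log_normal_prior(log_mean: float, log_sd: float) -> PriorSpec:
    return PriorSpec("log_normal", (log_mean, log_sd))


def log_pdf(spec: PriorSpec, x) -> np.ndarray:
    """Log density of ``spec`` at ``x`` (vectorized; -inf off support)."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    f, p = spec.family, spec.params
    if f == "gamma":
        a, rate = p
        m = x > 0
        xm = x[m]
        out[m] = a * np.log(rate) - special.gammaln(a) + (a - 1.0) * np.log(xm) - rate * xm
    elif f == "beta":
        al, be = p
        m = (x >= 0) & (x <= 1)
        xm = np.clip(x[m], 1e-300, 1.0)
        one_m = np.clip(1.0 - x[m], 1e-300, 1.0)
        out[m] = (
            -special.betaln(al, be) + (al - 1.0) * np.log(xm) + (be - 1.0) * np.log(one_m)
        )
        # density at the boundary is finite only if the exponent is zero
        if al < 1:
            out[x == 0] = np.inf
        if be < 1:
            out[x == 1] = np.inf
    elif f == "folded_normal":
        loc, s = p
        m = x >= 0
        xm = x[m]
        la = -0.5 * ((xm - loc) / s) ** 2
        lb = -0.5 * ((xm + loc) / s) ** 2
        out[m] = np.logaddexp(la, lb) - np.log(s) - 0.5 * _LOG_2PI
    elif f == "folded_student_t":
        df, loc, s = p
        m = x >= 0
        xm = x[m]
        lc = special.gammaln((df + 1) / 2) - special.gammaln(df / 2) - 0.5 * np.log(df * np.pi) - np.log(s)
        la = -0.5 * (df + 1) * np.log1p(((xm - loc) / s) ** 2 / df)
        lb = -0.5 * (df + 1) * np.log1p(((xm + loc) / s) ** 2 / df)
        out[m] = lc + np.logaddexp(la, lb)
    elif f == "log_normal":
        mu, s = p
        m = x > 0
        xm = x[m]
        lx = np.log(xm)
        out[m] = -lx - np.log(s) - 0.5 * _LOG_2PI - 0.5 * ((lx - mu) / s) ** 2
    return out if out.shape else float(out)


def grad_log_pdf(spec: PriorSpec, x) -> np.ndarray:
    """d/dx log pdf on the support interior (vectorized)."""
    x = np.asarray(x, dtype=float)
    f, p = spec.family, spec.params
    if f == "gamma":
        a, rate = p
        return (a - 1.0) / x - rate
    if f == "beta":
        al, be = p
        return (al - 1.0) / x - (be - 1.0) / (1.0 - x)
    if f == "folded_normal":
        loc, s = p
        la = -0.5 * ((x - loc) / s) ** 2
        lb = -0.5 * ((x + loc) / s) ** 2
        wa = 1.0 / (1.0 + np.exp(lb - la))
        ga = -(x - loc) / s**2
        gb = -(x + loc) / s**2
        return wa * ga + (1.0 - wa) * gb
    if f == "folded_student_t":
        df, loc, s = p
        la = -0.5 * (df + 1) * np.log1p(((x - loc) / s) ** 2 / df)
        lb = -0.5 * (df + 1) * np.log1p(((x + loc) / s) ** 2 / df)
        wa = 1.0 / (1.0 + np.exp(lb - la))
        ga = -(df + 1) * (x - loc) / (df * s**2 + (x - loc) ** 2)
        gb = -(df + 1) * (x + loc) / (df * s**2 + (x + loc) ** 2)
        return wa * ga + (1.0 - wa) * gb
    if f == "log_normal":
        mu, s = p
        return -1.0 / x - (np.log(x) - mu) / (x * s**2)
    raise PriorError(spec.family)


def sample(spec: PriorSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` samples; reproducible for a fixed seed or Generator."""
    if n < 1:
        raise PriorError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f, p = spec.family, spec.params
    if f == "gamma":
        a, rate = p
        return rng.gamma(a, 1.0 / rate, size=n)
    if f == "beta":
        return rng.beta(p[0], p[1], size=n)
    if f == "folded_normal":
        loc, s = p
        return np.abs(rng.normal(loc, s, size=n))
    if f == "folded_student_t":
        df, loc, s = p
        return np.abs(loc + s * rng.standard_t(df, size=n))
    if f == "log_normal":
        mu, s = p
        return np.exp(rng.normal(mu, s, size=n))
    raise PriorError(spec.family)


def scipy_dist(spec: PriorSpec):
    """The matching frozen scipy distribution (used as test oracle and for ppf)."""
    f, p = spec.family, spec.params
    if f == "gamma":
        return stats.gamma(p[0], scale=1.0 / p[1])
    if f == "beta":
        return stats.beta(p[0], p[1])
    if f == "folded_normal":
        return stats.foldnorm(abs(p[0]) / p[1], scale=p[1])
    if f == "folded_student_t":
        if p[1] != 0:
            raise PriorError("scipy oracle only for loc=0 folded-t")
        return stats.foldcauchy if False else _folded_t_frozen(p)
    if f == "log_normal":
        return stats.lognorm(p[1], scale=np.exp(p[0]))
    raise PriorError(spec.family)


class _folded_t_frozen:
    """Folded-t with loc=0: |s * t_df|; provides pdf/rvs for oracle use."""

    def __init__(self, p):
        self.df, self.loc, self.scale = p

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = 2.0 * stats.t.pdf(x / self.scale, self.df) / self.scale
        return np.where(x >= 0, out, 0.0)

    def logpdf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(x))


# The defaults of the Bayesian melting-curve models: weakly informative,
# keeping a, b on the scale of typical fits (a ~ 550, b ~ 10), the plateau
# small, and residuals shrunk towards zero.
DEFAULT_SIGMOID_PRIORS: dict[str, PriorSpec] = {
    "a": gamma_prior(7.0, 0.01),
    "b": gamma_prior(7.0, 0.4),
    "p": beta_prior(1.0, 20.0),
    "sigma": folded_normal_prior(0.0, 0.05),
}

# The GP deviation term gets strong shrinkage of its marginal sd (heavy-tailed
# folded-t, so large deviations remain reachable) and a log-normal length-scale
# prior that discourages both interpolating and near-constant functions.
DEFAULT_SEMIPARAMETRIC_PRIORS: dict[str, PriorSpec] = {
    **DEFAULT_SIGMOID_PRIORS,
    "v": folded_student_t_prior(3.0, 0.0, 0.5),
    "l": log_normal_prior(-0.5, 0.5),
}
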