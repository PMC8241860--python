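import numpy as np
import pytest
from scipy import stats

from tppbayes.evidence import (EvidenceError, classify_hits,
                               laplace_metropolis_from_draws,
                               laplace_metropolis_logml, posterior_model_prob,
                               sensitivity)
from tppbayes.models import ModelSpec
from tppbayes.sampling import (SamplerSettings, mean_function_bands,
                               run_ensemble, sample_posterior)


def _normal_mean_target(y, s, tau):
    def lp(X):
        th = X[:, 0]
        return (-0.5 * np.sum((y[None, :] - th[:, None]) ** 2, axis=1) / s**2
                - y.size * np.log(s) - 0.5 * y.size * np.log(2 * np.pi)
                - 0.5 * th**2 / tau**2 - np.log(tau) - 0.5 * np.log(2 * np.pi))
    post_var = 1.0 / (y.size / s**2 + 1.0 / tau**2)
    post_mean = post_var * np.sum(y) / s**2
    return lp, post_mean, np.sqrt(post_var)


def test_conjugate_posterior_moments_recovered():
    """Sampler moments match the analytic normal-mean posterior."""
    rng = np.random.default_rng(3)
    y = rng.normal(1.2, 0.8, 15)
    lp, m, sd = _normal_mean_target(y, 0.8, 2.0)
    init = rng.normal(m, sd, (16, 1))
    X, lpv, steps, rhat, ess, acc = run_ensemble(
        lp, init, SamplerSettings(seed=4, n_warmup=200, n_draws=300), ("theta",))
    ess_min = min(ess.values())
    mc_se = sd / np.sqrt(ess_min)
    assert X[:, 0].mean() == pytest.approx(m, abs=3 * mc_se)
    assert X[:, 0].std() == pytest.approx(sd, rel=0.1)
    assert max(rhat.values()) < 1.05


def test_same_seed_identical_draws(null_protein, lean_settings):
    spec = ModelSpec("sigmoid", "M0")
    f1 = sample_posterior(spec, null_protein, lean_settings)
    f2 = sample_posterior(spec, null_protein, lean_settings)
    np.testing.assert_array_equal(f1.samples[0].draws, f2.samples[0].draws)
    np.testing.assert_array_equal(f1.samples[0].log_post, f2.samples[0].log_post)


def test_diagnostics_recorded_per_parameter(sigmoid_m0_fit):
    s = sigmoid_m0_fit.samples[0]
    assert set(s.rhat) == {"a", "b", "p", "sigma"}
    assert set(s.ess_bulk) == {"a", "b", "p", "sigma"}
    assert np.all(s.draws[:, 0] > 0)            # constrained support respected
    assert np.all((s.draws[:, 2] > 0) & (s.draws[:, 2] < 1))


def test_undersampled_fit_is_flagged(null_protein):
    settings = SamplerSettings(n_walkers=16, n_warmup=2, n_draws=8, seed=1)
    fit = sample_posterior(ModelSpec("semiparametric", "M0"), null_protein, settings)
    assert fit.flagged


def test_mean_function_bands_nesting(sigmoid_m1_fit, null_protein):
    bands = mean_function_bands(sigmoid_m1_fit, null_protein)
    for cond in bands.conditions:
        lo50, hi50 = bands.lower[cond][0.5], bands.upper[cond][0.5]
        lo95, hi95 = bands.lower[cond][0.95], bands.upper[cond][0.95]
        assert np.all(lo95 <= lo50) and np.all(hi50 <= hi95)
        assert np.all(lo50 <= bands.median[cond]) and np.all(bands.median[cond] <= hi50)


def test_mean_function_bands_degenerate_draws(sigmoid_m0_fit, null_protein):
    import copy

    fit = copy.deepcopy(sigmoid_m0_fit)
    one = fit.samples[0].draws[:1]
    fit.samples[0].draws = np.repeat(one, 50, axis=0)
    bands = mean_function_bands(fit, null_protein)
    for cond in bands.conditions:
        np.testing.assert_allclose(bands.lower[cond][0.95], bands.upper[cond][0.95])
        np.testing.assert_allclose(bands.median[cond], bands.lower[cond][0.5])


def test_mean_function_bands_empty_draws_raise(sigmoid_m0_fit, null_protein):
    import copy

    fit = copy.deepcopy(sigmoid_m0_fit)
    fit.samples[0].draws = np.empty((0, 4))
    with pytest.raises(ValueError, match="empty"):
        mean_function_bands(fit, null_protein)


# ---------------------------------------------------------------------------
# evidence

def test_gaussian_identity_evidence():
    """On an exactly Gaussian target the estimator recovers the normalizer."""
    rng = np.random.default_rng(11)
    P, logZ = 3, -7.3
    A = rng.normal(0, 1, (P, P))
    cov = A @ A.T + np.eye(P)
    mean = rng.normal(0, 1, P)
    X = rng.multivariate_normal(mean, cov, size=4000)
    lp = logZ + stats.multivariate_normal.logpdf(X, mean, cov)
    est = laplace_metropolis_from_draws(X, lp)
    assert est == pytest.approx(logZ, abs=0.15)


def test_evidence_requires_enough_draws():
    X = np.random.default_rng(0).normal(0, 1, (50, 2))
    with pytest.raises(EvidenceError):
        laplace_metropolis_from_draws(X, np.zeros(50))


def test_evidence_flags_degenerate_covariance():
    X = np.zeros((500, 2))
    with pytest.raises(EvidenceError, match="rank-deficient"):
        laplace_metropolis_from_draws(X, np.zeros(500), ridge=0.0)


def test_evidence_parameterization_invariance():
    """Exponential-rate model: evidence agrees across two unconstrained transforms.

    y_i ~ Exp(theta), theta ~ Gamma(2, 1): the marginal likelihood is
    available in closed form through conjugacy.
    """
    rng = np.random.default_rng(23)
    y = rng.exponential(1 / 1.7, size=12)
    from scipy.special import gammaln

    a0, b0 = 2.0, 1.0
    n, sy = y.size, y.sum()
    exact = (a0 * np.log(b0) - gammaln(a0) + gammaln(a0 + n)
             - (a0 + n) * np.log(b0 + sy))

    def lp_log(X):   # x = log theta
        th = np.exp(X[:, 0])
        return (n * np.log(th) - th * sy
                + a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * np.log(th) - b0 * th
                + X[:, 0])

    def lp_sqrt(X):  # u = sqrt(theta), Jacobian 2u
        u = X[:, 0]
        th = u**2
        out = np.full(u.shape, -np.inf)
        ok = u > 0
        out[ok] = (n * np.log(th[ok]) - th[ok] * sy
                   + a0 * np.log(b0) - gammaln(a0)
                   + (a0 - 1) * np.log(th[ok]) - b0 * th[ok]
                   + np.log(2 * u[ok]))
        return out

    settings = SamplerSettings(seed=2, n_walkers=16, n_warmup=200, n_draws=300)
    init_log = np.log(rng.gamma(a0 + n, 1 / (b0 + sy), (16, 1)))
    X1, lp1, *_ = run_ensemble(lp_log, init_log, settings, ("x",))
    est1 = laplace_metropolis_from_draws(X1, lp1)
    init_sqrt = np.sqrt(np.exp(init_log))
    X2, lp2, *_ = run_ensemble(lp_sqrt, init_sqrt, settings, ("u",))
    est2 = laplace_metropolis_from_draws(X2, lp2)
    assert est1 == pytest.approx(exact, abs=0.1)
    assert est2 == pytest.approx(exact, abs=0.1)
    assert est1 == pytest.approx(est2, abs=0.1)


def test_m1_evidence_is_sum_of_condition_blocks(sigmoid_m1_fit):
    total = laplace_metropolis_logml(sigmoid_m1_fit)
    parts = [laplace_metropolis_from_draws(s.draws_unconstrained, s.log_post)
             for s in sigmoid_m1_fit.samples]
    assert total == pytest.approx(sum(parts), abs=1e-10)


@pytest.mark.parametrize("logml0,logml1,prior0,expected", [
    (5.0, 5.0, 0.99, 0.01),
    (0.0, np.log(99.0), 0.99, 0.5),
    (3.0, 3.0, 0.5, 0.5),
])
def test_posterior_model_prob_reference_points(logml0, logml1, prior0, expected):
    ev = posterior_model_prob(logml0, logml1, prior0)
    assert ev.posterior_prob_M1 == pytest.approx(expected, abs=1e-12)
    assert ev.log_bayes_factor_10 == pytest.approx(logml1 - logml0)


def test_posterior_model_prob_monotone_and_saturating():
    probs = [posterior_model_prob(0.0, b).posterior_prob_M1
             for b in (-5, 0, 5, 10, 20)]
    assert all(p2 > p1 for p1, p2 in zip(probs, probs[1:]))
    assert posterior_model_prob(0.0, 1e6).posterior_prob_M1 == 1.0
    assert posterior_model_prob(1e6, 0.0).posterior_prob_M1 == 0.0
    with pytest.raises(ValueError):
        posterior_model_prob(0.0, 0.0, prior_prob_M0=1.0)


def test_classify_hits_strict_boundary():
    probs = {"A": 0.999, "B": 0.99, "C": 0.5}
    hits, flagged = classify_hits(probs, threshold=0.99)
    assert hits == {"A"}
    assert flagged == set()
    assert classify_hits({}, 0.99)[0] == set()
    hits, flagged = classify_hits(probs, 0.99, flagged={"A"})
    assert hits == set() and flagged == {"A"}


def test_sensitivity_proportions():
    assert sensitivity({"a", "b"}, {"a", "b"}) == 1.0
    assert sensitivity({"c"}, {"a", "b"}) == 0.0
    assert sensitivity({"a", "c"}, {"a", "b", "d", "e"}) == 0.25
    with pytest.raises(ValueError):
        sensitivity({"a"}, set())
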