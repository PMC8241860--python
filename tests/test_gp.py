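import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from tppbayes.gp import (gp_conditional_mean, gp_marginal_loglik,
                         gp_marginal_loglik_batch, gp_marginal_loglik_grad,
                         reduced_rank_loglik, se_covariance)

T10 = np.linspace(37.0, 67.0, 10)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(8)
    y = 1.0 - 0.02 * (T10 - 37.0) + 0.05 * rng.standard_normal(10)
    mean = np.full(10, 0.7)
    return y, mean


def test_se_covariance_closed_forms():
    C = se_covariance(np.array([0.0, 1.0, 100.0]), v=1.0, l=1.0)
    np.testing.assert_allclose(np.diag(C), 1.0)
    assert C[0, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)
    assert C[0, 2] == 0.0  # |dT| = 100 l underflows to an exact zero
    np.testing.assert_allclose(C, C.T)
    # repeated temperatures (replicate copies) share the full covariance
    C2 = se_covariance(np.array([40.0, 40.0]), v=0.3, l=5.0)
    assert C2[0, 1] == pytest.approx(0.09, rel=1e-12)
    w = np.linalg.eigvalsh(se_covariance(T10, 0.5, 4.0))
    assert np.all(w > -1e-10)


def test_se_covariance_rejects_bad_hyper():
    with pytest.raises(ValueError):
        se_covariance(T10, v=1.0, l=0.0)
    with pytest.raises(ValueError):
        se_covariance(T10, v=-1.0, l=1.0)


def test_marginal_loglik_equals_dense_mvn(toy):
    y, mean = toy
    v, l, sg = 0.3, 6.0, 0.05
    K = se_covariance(T10, v, l) + sg**2 * np.eye(10)
    ref = stats.multivariate_normal.logpdf(y, mean, K)
    assert gp_marginal_loglik(y, mean, T10, v, l, sg) == pytest.approx(ref, abs=1e-10)


def test_marginal_loglik_v_zero_is_iid_normal(toy):
    y, mean = toy
    sg = 0.07
    ref = stats.norm.logpdf(y, mean, sg).sum()
    assert gp_marginal_loglik(y, mean, T10, 0.0, 3.0, sg) == pytest.approx(ref, abs=1e-10)


def test_marginal_loglik_scalar_case():
    ref = stats.norm.logpdf(0.8, 0.7, np.sqrt(0.3**2 + 0.05**2))
    got = gp_marginal_loglik(np.array([0.8]), np.array([0.7]), np.array([50.0]),
                             0.3, 5.0, 0.05)
    assert got == pytest.approx(ref, abs=1e-12)


def test_marginal_loglik_matches_monte_carlo(toy):
    """Marginalizing mu explicitly by Monte Carlo recovers the closed form."""
    y, mean = toy
    y5, m5, T5 = y[:5], mean[:5], T10[:5]
    v, l, sg = 0.3, 6.0, 0.05
    rng = np.random.default_rng(17)
    M = 200_000
    L = np.linalg.cholesky(se_covariance(T5, v, l) + 1e-12 * np.eye(5))
    mu = (L @ rng.standard_normal((5, M))).T
    ll = (-0.5 * np.sum((y5 - m5 - mu) ** 2, axis=1) / sg**2
          - 5 * np.log(sg) - 2.5 * np.log(2 * np.pi))
    mc = logsumexp(ll) - np.log(M)
    w = np.exp(ll - ll.max())
    mc_se = np.std(w) / (np.mean(w) * np.sqrt(M))
    dense = gp_marginal_loglik(y5, m5, T5, v, l, sg)
    assert abs(dense - mc) < 3 * mc_se


def test_marginal_loglik_permutation_invariance(toy):
    y, mean = toy
    v, l, sg = 0.2, 5.0, 0.06
    perm = np.random.default_rng(3).permutation(10)
    base = gp_marginal_loglik(y, mean, T10, v, l, sg)
    permuted = gp_marginal_loglik(y[perm], mean[perm], T10[perm], v, l, sg)
    assert permuted == pytest.approx(base, abs=1e-9)


def test_marginal_loglik_batch_matches_scalar(toy):
    y, mean = toy
    d2 = (T10[:, None] - T10[None, :]) ** 2
    v = np.array([0.1, 0.3, 1.0])
    l = np.array([2.0, 6.0, 10.0])
    sg = np.array([0.05, 0.08, 0.02])
    means = np.tile(mean, (3, 1))
    batch = gp_marginal_loglik_batch(y, means, d2, v, l, sg)
    for i in range(3):
        assert batch[i] == pytest.approx(
            gp_marginal_loglik(y, mean, T10, v[i], l[i], sg[i]), abs=1e-8)


def test_marginal_loglik_gradient_matches_finite_differences(toy):
    y, mean = toy
    v, l, sg = 0.25, 5.0, 0.06
    _, _, dv, dl, ds = gp_marginal_loglik_grad(y, mean, T10, v, l, sg)
    eps = 1e-6
    num_v = (gp_marginal_loglik(y, mean, T10, v + eps, l, sg)
             - gp_marginal_loglik(y, mean, T10, v - eps, l, sg)) / (2 * eps)
    num_l = (gp_marginal_loglik(y, mean, T10, v, l + eps, sg)
             - gp_marginal_loglik(y, mean, T10, v, l - eps, sg)) / (2 * eps)
    num_s = (gp_marginal_loglik(y, mean, T10, v, l, sg + eps)
             - gp_marginal_loglik(y, mean, T10, v, l, sg - eps)) / (2 * eps)
    assert dv == pytest.approx(num_v, rel=1e-5)
    assert dl == pytest.approx(num_l, rel=1e-5)
    assert ds == pytest.approx(num_s, rel=1e-5)


def test_conditional_mean_zero_cases(toy):
    y, mean = toy
    grid = np.array([40.0, 50.0, 60.0])
    np.testing.assert_allclose(
        gp_conditional_mean(y, mean, T10, 0.0, 5.0, 0.05, grid), 0.0)
    np.testing.assert_allclose(
        gp_conditional_mean(y, y, T10, 0.3, 5.0, 0.05, grid), 0.0, atol=1e-12)


def test_conditional_mean_dense_oracle(toy):
    y, mean = toy
    v, l, sg = 0.3, 6.0, 0.05
    grid = np.array([40.0, 50.0, 60.0])
    K = se_covariance(T10, v, l) + sg**2 * np.eye(10)
    Kstar = v**2 * np.exp(-((grid[:, None] - T10[None, :]) ** 2) / (2 * l**2))
    direct = Kstar @ np.linalg.solve(K, y - mean)
    got = gp_conditional_mean(y, mean, T10, v, l, sg, grid)
    np.testing.assert_allclose(got, direct, atol=1e-12)


def test_conditional_mean_interpolates_as_sigma_vanishes(toy):
    y, mean = toy
    got = gp_conditional_mean(y, mean, T10, 0.5, 6.0, 1e-7, T10)
    np.testing.assert_allclose(got, y - mean, atol=1e-4)


def test_reduced_rank_converges_to_dense(toy):
    y, mean = toy
    v, l, sg = 0.3, 6.0, 0.05
    dense = gp_marginal_loglik(y, mean, T10, v, l, sg)
    assert reduced_rank_loglik(y, mean, T10, v, l, sg, m_basis=64,
                               boundary_factor=3.0) == pytest.approx(dense, abs=1e-3)
    errs = [abs(reduced_rank_loglik(y, mean, T10, v, l, sg, m_basis=m,
                                    boundary_factor=3.0) - dense)
            for m in (8, 16, 32, 64)]
    assert all(errs[i + 1] <= errs[i] + 1e-9 for i in range(3))


def test_reduced_rank_v_zero_is_iid(toy):
    y, mean = toy
    sg = 0.07
    ref = stats.norm.logpdf(y, mean, sg).sum()
    assert reduced_rank_loglik(y, mean, T10, 0.0, 3.0, sg) == pytest.approx(ref, abs=1e-10)


def test_reduced_rank_rejects_bad_arguments(toy):
    y, mean = toy
    with pytest.raises(ValueError):
        reduced_rank_loglik(y, mean, T10, 0.3, 6.0, 0.05, m_basis=2)
    with pytest.raises(ValueError):
        reduced_rank_loglik(y, mean, T10, 0.3, 6.0, 0.05, boundary_factor=0.5)


def test_reduced_rank_batch_matches_dense(toy):
    from tppbayes.gp import reduced_rank_loglik_batch

    y, mean = toy
    Ts = T10 / 9.0  # standardized-scale inputs, as the model layer uses
    v = np.array([0.1, 0.3, 0.8])
    l = np.array([0.3, 0.6, 1.2])
    sg = np.array([0.05, 0.07, 0.03])
    batch = reduced_rank_loglik_batch(y, np.tile(mean, (3, 1)), Ts, v, l, sg,
                                      m_basis=64, boundary_factor=3.0)
    for i in range(3):
        dense = gp_marginal_loglik(y, mean, Ts, v[i], l[i], sg[i])
        assert batch[i] == pytest.approx(dense, abs=1e-4)


def test_reduced_rank_backend_reproduces_dense_posterior():
    """Sampling with the reduced-rank backend gives the same evidence as dense."""
    import tppbayes as tb
    from tppbayes.evidence import laplace_metropolis_logml
    from tppbayes.models import ModelSpec
    from tppbayes.sampling import SamplerSettings, sample_posterior

    ds, _ = tb.simulate_dataset(1, {"null_sigmoid": 1.0}, seed=3)
    prot = next(iter(ds.proteins.values()))
    logml = {}
    for backend in ("dense", "reduced_rank"):
        st = SamplerSettings(seed=5, n_walkers=32, n_warmup=120, n_draws=150,
                             gp_backend=backend)
        fit = sample_posterior(ModelSpec("semiparametric", "M0"), prot, st)
        logml[backend] = laplace_metropolis_logml(fit)
    assert logml["reduced_rank"] == pytest.approx(logml["dense"], abs=1.0)
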