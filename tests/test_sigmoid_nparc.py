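import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import stats

from tppbayes.data import ProteinMeltingData, TPPDataset
from tppbayes.sigmoid import (LSFit, estimate_effective_dof, fit_sigmoid_ls,
                              nparc_f_statistic, nparc_pvalues,
                              residual_correlation_matrix, sigmoid)
from tppbayes.simulate import Design, simulate_protein
from conftest import make_truth


def test_sigmoid_midpoint_value():
    # at T = a/b the exponential term is 1, so S = (1 + p)/2
    assert sigmoid(55.0, 550.0, 10.0, 0.1) == pytest.approx(0.55, rel=1e-12)


def test_sigmoid_limit_at_low_temperature():
    assert sigmoid(1e-9, 550.0, 10.0, 0.1) == pytest.approx(1.0, abs=1e-12)


def test_sigmoid_matches_high_precision_evaluation():
    a, b, p, T = 1000.0, 20.0, 0.05, 60.0
    expected = float((1 - np.longdouble(p)) /
                     (1 + np.exp(np.longdouble(b) - np.longdouble(a) / np.longdouble(T)))
                     + np.longdouble(p))
    assert sigmoid(T, a, b, p) == pytest.approx(expected, rel=1e-14)


def test_sigmoid_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        sigmoid(0.0, 550.0, 10.0, 0.1)
    with pytest.raises(ValueError):
        sigmoid(np.array([37.0, -1.0]), 550.0, 10.0, 0.1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=st.floats(50, 3000), b=st.floats(1, 60), p=st.floats(0.001, 0.4))
def test_sigmoid_decreasing_and_bounded(a, b, p):
    # monotone decreasing (strictly so away from float saturation at the
    # asymptotes); the midpoint a/b is kept inside the evaluated range
    assume(20.0 < a / b < 90.0)
    T = np.linspace(5.0, 95.0, 200)
    S = sigmoid(T, a, b, p)
    assert np.all(np.diff(S) <= 0)
    assert S[0] > S[-1]
    strict = (S < 1.0 - 1e-12) & (S > p + 1e-12)  # away from both asymptotes
    assert np.all(np.diff(S[strict]) < 0)
    assert np.all((S >= p) & (S <= 1))  # open bounds saturate in float64


def _noiseless_protein(a=620.0, tm=51.0, p=0.08):
    truth = make_truth(a=a, tm=tm, p=p, sigma=0.0)
    return simulate_protein(truth, Design(), seed=1), truth


def test_noiseless_recovery():
    prot, truth = _noiseless_protein()
    fit = fit_sigmoid_ls(prot, "M0")
    assert fit.converged
    assert fit.rss < 1e-10
    got = fit.params["pooled"]
    want = truth.params["control"]
    assert got.a == pytest.approx(want["a"], rel=1e-4)
    assert got.b == pytest.approx(want["b"], rel=1e-4)
    assert got.p == pytest.approx(want["p"], rel=1e-3)


def test_identical_conditions_nesting_degeneracy():
    prot, _ = _noiseless_protein()
    fit0 = fit_sigmoid_ls(prot, "M0")
    fit1 = fit_sigmoid_ls(prot, "M1")
    assert fit1.rss <= fit0.rss + 1e-9
    assert fit1.rss == pytest.approx(fit0.rss, abs=1e-8)


def test_m1_never_worse_than_m0_on_noisy_data():
    design = Design()
    for seed in range(5):
        truth = make_truth(sigma=0.06, tm_shift=3.0 if seed % 2 else 0.0)
        prot = simulate_protein(truth, design, seed=seed)
        f0 = fit_sigmoid_ls(prot, "M0")
        f1 = fit_sigmoid_ls(prot, "M1")
        assert f1.rss <= f0.rss + 1e-9


@pytest.mark.parametrize("rss0,rss1,d1,d2,expected", [
    (1.0, 1.0, 2.0, 4.0, 0.0),
    (3.0, 1.0, 2.0, 4.0, 4.0),
    (2.0, 1.0, 5.0, 5.0, 1.0),
])
def test_f_statistic_arithmetic(rss0, rss1, d1, d2, expected):
    assert nparc_f_statistic(rss0, rss1, d1, d2) == pytest.approx(expected)


def test_f_statistic_rejects_degenerate():
    with pytest.raises(ValueError):
        nparc_f_statistic(1.0, 0.0, 2.0, 4.0)
    with pytest.raises(ValueError):
        nparc_f_statistic(1.0, 1.0, 0.0, 4.0)


@pytest.mark.parametrize("d1,d2", [(4, 32), (2, 10)])
def test_effective_dof_recovery(d1, d2):
    F = stats.f.rvs(d1, d2, size=5000, random_state=99)
    d1e, d2e = estimate_effective_dof(F)
    assert d1e == pytest.approx(d1, rel=0.2)
    assert d2e == pytest.approx(d2, rel=0.2)


def test_effective_dof_error_paths():
    with pytest.raises(ValueError, match="at least 100"):
        estimate_effective_dof(np.ones(50) * 2.0)
    with pytest.raises(ValueError, match="identical"):
        estimate_effective_dof(np.ones(200) * 2.0)


def test_pvalues_trivials():
    p, p_adj = nparc_pvalues(np.array([0.0]), 4.0, 30.0)
    assert p[0] == pytest.approx(1.0)
    # all-equal statistics give all-equal adjusted p-values
    p, p_adj = nparc_pvalues(np.full(6, 2.5), 4.0, 30.0)
    assert np.allclose(p_adj, p_adj[0])
    # NaN statistics propagate
    p, p_adj = nparc_pvalues(np.array([1.0, np.nan, 3.0]), 4.0, 30.0)
    assert np.isnan(p[1]) and np.isnan(p_adj[1])


def test_bh_adjustment_worked_example():
    # hand-computed step-up values for p = (.005, .04, .03, .01, .9):
    # sorted .005->.025, .01->.025, .03->.05, .04->.05, .9->.9
    d1e, d2e = 4.0, 30.0
    raw = np.array([0.005, 0.04, 0.03, 0.01, 0.9])
    F = stats.f.isf(raw, d1e, d2e)
    p, p_adj = nparc_pvalues(F, d1e, d2e)
    np.testing.assert_allclose(p, raw, rtol=1e-9)
    np.testing.assert_allclose(p_adj, [0.025, 0.05, 0.05, 0.025, 0.9], rtol=1e-9)


def _fake_dataset_and_fits(residual_matrix, design):
    """Wrap a (n_proteins, D) residual matrix into dataset + LSFit objects."""
    n, D = residual_matrix.shape
    T = np.asarray(design.temperatures)
    proteins, fits = {}, {}
    for i in range(n):
        pid = f"P{i}"
        obs = {(c, 1): np.ones(D) for c in design.conditions}
        proteins[pid] = ProteinMeltingData(pid, T, design.conditions, obs)
        res = {c: residual_matrix[i].copy() for c in design.conditions}
        fits[pid] = LSFit(params={}, rss=1.0, residuals=res, converged=True,
                          n_obs=2 * D, n_params=6)
    return TPPDataset(proteins=proteins), fits


def test_residual_matrix_shape_and_trivials(design):
    rng = np.random.default_rng(3)
    ds, fits = _fake_dataset_and_fits(rng.standard_normal((50, 10)), design)
    C = residual_correlation_matrix(ds, fits)
    assert C.shape == (10, 10)
    np.testing.assert_allclose(np.diag(C), 1.0)
    np.testing.assert_allclose(C, C.T, atol=1e-12)
    assert np.all(np.abs(C) <= 1 + 1e-12)


def test_residual_matrix_iid_null(design):
    rng = np.random.default_rng(4)
    ds, fits = _fake_dataset_and_fits(rng.standard_normal((1000, 10)), design)
    C = residual_correlation_matrix(ds, fits)
    off = C - np.diag(np.diag(C))
    assert np.max(np.abs(off)) < 0.1


def test_residual_matrix_ar1_structure(design):
    rng = np.random.default_rng(5)
    n, D, rho = 1000, 10, 0.8
    R = np.zeros((n, D))
    R[:, 0] = rng.standard_normal(n)
    for j in range(1, D):
        R[:, j] = rho * R[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    ds, fits = _fake_dataset_and_fits(R, design)
    C = residual_correlation_matrix(ds, fits)
    lag1 = np.mean(np.diag(C, k=1))
    lag3 = np.mean(np.diag(C, k=3))
    assert lag1 > lag3


def test_residual_matrix_needs_three_proteins(design):
    rng = np.random.default_rng(6)
    ds, fits = _fake_dataset_and_fits(rng.standard_normal((2, 10)), design)
    with pytest.raises(ValueError, match="3 proteins"):
        residual_correlation_matrix(ds, fits)
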