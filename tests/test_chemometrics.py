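"""OPLS-DA: structural identities, CV Q2, VIP, permutation null."""

import numpy as np
import pytest

from lipidscreen.chemometrics import (
    ScalingSpec,
    cross_validated_q2,
    fit_opls,
    permutation_validation,
    select_markers,
    vip_scores,
)


def nipals_pls1(x, y, tol=1e-12, max_iter=500):
    """Independent oracle: first NIPALS PLS1 component on centered/scaled
    data.  Coded from the classic algorithm, no shared code with the
    package implementation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = (x - x.mean(0)) / x.std(0, ddof=1)
    yc = y - y.mean()
    w = xs.T @ yc
    w = w / np.sqrt((w**2).sum())
    for _ in range(max_iter):
        t = xs @ w
        q = (yc @ t) / (t @ t)
        w_new = xs.T @ yc * q  # for PLS1 the loop converges immediately
        w_new /= np.sqrt((w_new**2).sum())
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    t = xs @ w
    p = xs.T @ t / (t @ t)
    return w, t, p


@pytest.fixture()
def signal_data():
    """60 samples x 20 features; 3 informative features, fixed seed."""
    rng = np.random.default_rng(21)
    y = np.array([0] * 30 + [1] * 30)
    x = rng.normal(size=(60, 20))
    x[:, 0] += 2.0 * y
    x[:, 1] -= 1.5 * y
    x[:, 2] += 1.0 * y
    return x, y


def test_perfect_single_predictor():
    rng = np.random.default_rng(0)
    y = np.array([0] * 5 + [1] * 5)
    x = y.astype(float)[:, None] + 0.0
    model = fit_opls(x, y, n_ortho=0)
    assert model.r2y == pytest.approx(1.0, abs=1e-10)


def test_orthogonal_scores_uncorrelated_with_y(signal_data):
    x, y = signal_data
    for n_ortho in (1, 2, 3):
        model = fit_opls(x, y, n_ortho=n_ortho)
        yc = y - y.mean()
        for j in range(model.n_ortho):
            t_o = model.t_ortho[:, j]
            corr = abs(np.corrcoef(t_o, yc)[0, 1])
            assert corr < 1e-8


def test_vip_identity_and_symmetry(signal_data):
    x, y = signal_data
    model = fit_opls(x, y, n_ortho=1)
    vip = vip_scores(model)
    assert vip.sum() > 0
    assert (vip**2).sum() == pytest.approx(x.shape[1], abs=1e-6)
    # all-equal weights -> VIP exactly 1 everywhere
    rng = np.random.default_rng(5)
    y2 = np.array([0] * 10 + [1] * 10)
    base = rng.normal(size=20)
    x2 = np.column_stack([base + 0.5 * y2 + rng.normal(0, 1e-9, 20)
                          for _ in range(4)])
    m2 = fit_opls(x2, y2, n_ortho=0)
    assert np.allclose(vip_scores(m2), 1.0, atol=1e-3)


def test_predictive_component_equals_nipals_pls1():
    """With no orthogonal components the predictive component must match
    an independently coded NIPALS PLS1 first component (up to sign)."""
    rng = np.random.default_rng(17)
    x = rng.normal(size=(10, 6))
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    x[:, 2] += 1.2 * y
    model = fit_opls(x, y, n_ortho=0)
    w_ref, t_ref, p_ref = nipals_pls1(x, y)
    sign = np.sign(w_ref @ model.w)
    np.testing.assert_allclose(model.w, sign * w_ref, atol=1e-10)
    np.testing.assert_allclose(model.t, sign * t_ref, atol=1e-8)
    np.testing.assert_allclose(model.p, sign * p_ref, atol=1e-8)


def test_sign_convention_class1_positive(signal_data):
    x, y = signal_data
    model = fit_opls(x, y)
    assert model.t[y == 1].mean() > 0


def test_sample_order_invariance(signal_data):
    x, y = signal_data
    rng = np.random.default_rng(9)
    perm = rng.permutation(len(y))
    m1 = fit_opls(x, y, n_ortho=1)
    m2 = fit_opls(x[perm], y[perm], n_ortho=1)
    assert m1.r2x == pytest.approx(m2.r2x, abs=1e-10)
    assert m1.r2y == pytest.approx(m2.r2y, abs=1e-10)
    np.testing.assert_allclose(np.abs(m1.w), np.abs(m2.w), atol=1e-10)


def test_reconstruction_consistent_with_r2x(signal_data):
    x, y = signal_data
    model = fit_opls(x, y, n_ortho=1)
    xs = model.scaling.transform(x)
    recon = np.outer(model.t, model.p)
    for j in range(model.n_ortho):
        recon += np.outer(model.t_ortho[:, j], model.p_ortho[j])
    r2x = 1 - ((xs - recon) ** 2).sum() / (xs**2).sum()
    assert r2x == pytest.approx(model.r2x, abs=1e-10)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match="two classes"):
        fit_opls(np.random.default_rng(0).normal(size=(6, 3)), [1] * 6)
    with pytest.raises(ValueError, match="variance"):
        fit_opls(np.ones((6, 3)), [0, 0, 0, 1, 1, 1])
    with pytest.raises(ValueError, match=">= 3"):
        fit_opls(np.random.default_rng(0).normal(size=(5, 3)), [0, 0, 1, 1, 1])


@pytest.fixture()
def separable_data():
    """Wide-margin two-class data: the class difference dwarfs the noise."""
    rng = np.random.default_rng(33)
    y = np.array([0] * 25 + [1] * 25)
    x = rng.normal(0, 0.05, size=(50, 8))
    x[:, 0] += 1.0 * y
    x[:, 1] -= 1.0 * y
    return x, y


def test_q2_strong_signal_and_bounds(separable_data, signal_data):
    x, y = separable_data
    q2 = cross_validated_q2(x, y, folds=7, seed=11)
    model = fit_opls(x, y, n_ortho=1)
    assert q2 > 0.9  # essentially noiseless separable structure
    assert q2 <= model.r2y + 1e-6
    # the bound also holds on noisier data
    xn, yn = signal_data
    assert cross_validated_q2(xn, yn, folds=7, seed=11) <= fit_opls(
        xn, yn).r2y + 1e-6


def test_q2_loo_mode(separable_data):
    x, y = separable_data
    q2 = cross_validated_q2(x, y, folds=len(y), seed=0)
    assert q2 > 0.9


def test_q2_permutation_null(signal_data):
    """Label permutations destroy the class signal: the null Q2 is at or
    below zero on average (cross-validated PLS has a negative null bias
    at p ~ n) and the real labels beat every permutation."""
    x, y = signal_data
    out = permutation_validation(x, y, n_perm=30, seed=2, folds=7)
    null = np.array(out["null_q2y"])
    assert -0.8 < null.mean() < 0.05
    assert out["observed_q2y"] > null.max()
    assert out["p_q2y"] <= 1 / (30 + 1) + 1e-12


def test_permutation_reproducible(signal_data):
    x, y = signal_data
    a = permutation_validation(x, y, n_perm=20, seed=4)
    b = permutation_validation(x, y, n_perm=20, seed=4)
    assert a == b


def test_select_markers_thresholds(signal_data):
    x, y = signal_data
    model = fit_opls(x, y)
    model.feature_ids = [f"feat{i}" for i in range(x.shape[1])]
    vip = vip_scores(model)
    assert select_markers(model, threshold=float(vip.max())) == []
    assert len(select_markers(model, threshold=0.0)) == x.shape[1]
    panel = select_markers(model, threshold=1.0)
    # the strongest planted predictor attains the maximal VIP
    assert panel[0] == f"feat{int(np.argmax(vip))}" == "feat0"


def test_scaling_modes(signal_data):
    x, y = signal_data
    for mode in ("uv", "pareto", "none"):
        model = fit_opls(x, y, scaling=ScalingSpec(mode=mode))
        assert 0 <= model.r2y <= 1
    with pytest.raises(ValueError):
        fit_opls(x, y, scaling=ScalingSpec(mode="bogus"))
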