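"""Decision-function arithmetic, sigmoid calibration and classification.

The hand-evaluated kernel expansion and the sklearn decision function
serve as mutually independent routes to D(x); the sigmoid fit is checked
by parameter recovery against its own generative model and by a
grid-search lower bound on the negative log likelihood.
"""

import numpy as np
import pytest

from swallowsense.svm import (PlattParams, SwallowSVM, fit_sigmoid,
                              kernel_decision, sigmoid_nll, sigmoid_posterior)


# -- decision function -------------------------------------------------------

def test_hand_set_linear_model_matches_pencil_arithmetic():
    # 2 support vectors, linear kernel: D(x) = 0.5*(x.[1,0]) - 0.5*(x.[0,1]) + 0.1
    sv = np.array([[1.0, 0.0], [0.0, 1.0]])
    coef = np.array([0.5, -0.5])
    d = kernel_decision(np.array([[2.0, 1.0]]), sv, coef, 0.1, kernel="linear")
    assert d[0] == pytest.approx(0.5 * 2.0 - 0.5 * 1.0 + 0.1)


def test_hand_set_rbf_model_matches_pencil_arithmetic():
    sv = np.array([[0.0], [2.0]])
    coef = np.array([1.0, -1.0])
    x = np.array([[1.0]])
    expected = np.exp(-1.0) - np.exp(-1.0) + 0.25  # gamma=1, both distances 1
    d = kernel_decision(x, sv, coef, 0.25, kernel="rbf", gamma=1.0)
    assert d[0] == pytest.approx(expected)


def test_decision_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="dimension"):
        kernel_decision(np.zeros((1, 3)), np.zeros((2, 2)), np.ones(2), 0.0)


def test_decision_matches_sklearn_oracle(fitted_svm):
    model, X, _, X_te, _ = fitted_svm
    ours = model.decision_function(X_te)
    oracle = model._sklearn_svc_.decision_function(model.scaler_.transform(X_te))
    np.testing.assert_allclose(ours, oracle, atol=1e-8)


def test_linearly_separable_toy_perfect_training_accuracy():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-3, 0.5, (40, 2)), rng.normal(3, 0.5, (40, 2))])
    y = np.array([-1] * 40 + [1] * 40)
    model = SwallowSVM(kernel="linear", calibration_folds=3).fit(X, y)
    assert (np.sign(model.decision_function(X)) == y).all()


def test_label_flip_negates_decision():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(-1, 1.0, (60, 3)), rng.normal(1, 1.0, (60, 3))])
    y = np.array([-1] * 60 + [1] * 60)
    d_pos = SwallowSVM(kernel="rbf").fit(X, y).decision_function(X)
    d_neg = SwallowSVM(kernel="rbf").fit(X, -y).decision_function(X)
    # exact up to the libsvm solver tolerance (1e-3)
    np.testing.assert_allclose(d_pos, -d_neg, atol=1e-2)


def test_single_class_training_rejected():
    X = np.random.default_rng(0).normal(size=(20, 2))
    with pytest.raises(ValueError, match="both classes"):
        SwallowSVM().fit(X, np.ones(20))


def test_abs_decision_tracks_geometric_distance():
    """With a linear kernel, D(x)/margin_scale is the signed distance to
    the boundary, so |D| must increase with distance on a grid."""
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(-2, 0.6, (80, 2)), rng.normal(2, 0.6, (80, 2))])
    y = np.array([-1] * 80 + [1] * 80)
    model = SwallowSVM(kernel="linear").fit(X, y)
    grid = np.column_stack([np.linspace(-4, 4, 41), np.zeros(41)])
    d = model.decision_function(grid)
    # recover the separating direction from two decision evaluations
    w_norm = model.margin_scale_
    assert w_norm > 0
    geo = np.abs(d) / w_norm
    r = np.corrcoef(np.abs(d), geo)[0, 1]
    assert r > 0.999  # proportional by construction; checks consistency
    # and |D| grows monotonically away from the zero crossing
    zero = np.argmin(np.abs(d))
    assert np.all(np.diff(np.abs(d[zero:])) >= -1e-9)
    assert np.all(np.diff(np.abs(d[:zero + 1])) <= 1e-9)


def test_decision_positive_for_most_heldout_swallows(fitted_svm):
    model, _, _, X_te, y_te = fitted_svm
    d = model.decision_function(X_te)
    assert (d[y_te == 1] > 0).mean() > 0.5


# -- posterior sigmoid -------------------------------------------------------

def test_sigmoid_midpoint():
    assert sigmoid_posterior(0.0, PlattParams(-1.0, 0.0)) == pytest.approx(0.5)


def test_sigmoid_limits_and_monotonicity():
    params = PlattParams(-2.0, 0.3)
    d = np.linspace(-50, 50, 201)
    p = sigmoid_posterior(d, params)
    assert p[0] < 1e-9 and p[-1] > 1 - 1e-9
    assert np.all(np.diff(p) >= 0)


def test_posterior_complement_identity(fitted_svm):
    model, _, _, X_te, _ = fitted_svm
    proba = model.predict_proba(X_te)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((proba >= 0) & (proba <= 1))


def test_platt_params_require_negative_slope():
    with pytest.raises(ValueError):
        PlattParams(0.5, 0.0)


def test_sigmoid_parameter_recovery():
    rng = np.random.default_rng(3)
    a_true, b_true = -0.8, 0.2
    d = rng.normal(0.0, 1.5, 5000)
    p = 1.0 / (1.0 + np.exp(a_true * d + b_true))
    y = np.where(rng.random(5000) < p, 1, -1)
    fit = fit_sigmoid(d, y)
    assert fit.sigmoid_a == pytest.approx(a_true, abs=0.05)
    assert fit.sigmoid_b == pytest.approx(b_true, abs=0.05)


def test_fitted_nll_beats_grid_search():
    rng = np.random.default_rng(4)
    d = rng.normal(0.0, 1.5, 2000)
    p = 1.0 / (1.0 + np.exp(-1.2 * d + 0.1))
    y = np.where(rng.random(2000) < p, 1, -1)
    fit = fit_sigmoid(d, y)
    nll_fit = sigmoid_nll(d, y, fit.sigmoid_a, fit.sigmoid_b)
    grid = min(sigmoid_nll(d, y, a, b)
               for a in np.linspace(-3.0, -0.2, 100)
               for b in np.linspace(-1.0, 1.0, 100))
    assert nll_fit <= grid + 1e-9


def test_sigmoid_fit_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        fit_sigmoid(np.ones(10), np.ones(10))


# -- classification ----------------------------------------------------------

def test_boundary_posterior_counts_as_swallow():
    """A cycle exactly at Pth is classified as a swallow (the 'otherwise'
    branch of the decision rule)."""
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(-2, 0.7, (50, 2)), rng.normal(2, 0.7, (50, 2))])
    y = np.array([-1] * 50 + [1] * 50)
    model = SwallowSVM().fit(X, y)
    post = model.posterior(X)
    labels = np.where(post >= 0.5, 1, -1)
    np.testing.assert_array_equal(model.predict(X), labels)
    # explicit boundary: threshold set exactly at an attained posterior
    pth = float(model.posterior(X[:1])[0])
    assert model.predict(X[:1], posterior_threshold=pth)[0] == 1


def test_pth_zero_flags_everything(fitted_svm):
    model, _, _, X_te, _ = fitted_svm
    assert (model.predict(X_te, posterior_threshold=0.0) == 1).all()
    with pytest.raises(ValueError):
        model.predict(X_te, posterior_threshold=1.5)


def test_raising_pth_never_increases_detections(fitted_svm):
    model, _, _, X_te, _ = fitted_svm
    counts = [(model.predict(X_te, posterior_threshold=pth) == 1).sum()
              for pth in np.linspace(0.05, 0.95, 19)]
    assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))


def test_posterior_histogram_bimodal(fitted_svm):
    """Posteriors pile up near 0 for normal cycles and near 1 for swallow
    cycles on held-out data."""
    model, _, _, X_te, y_te = fitted_svm
    post = model.posterior(X_te)
    normals = post[y_te == 0]
    swallows = post[y_te == 1]
    assert np.median(normals) < 0.2
    assert np.median(swallows) > 0.8
    assert (normals < 0.1).mean() > 0.5
    assert (swallows > 0.9).mean() > 0.5


def test_model_json_round_trip(tmp_path, fitted_svm):
    model, _, _, X_te, _ = fitted_svm
    path = tmp_path / "model.json"
    model.to_json(path)
    back = SwallowSVM.from_json(path)
    np.testing.assert_allclose(back.decision_function(X_te),
                               model.decision_function(X_te), atol=1e-12)
    np.testing.assert_allclose(back.posterior(X_te), model.posterior(X_te),
                               atol=1e-12)
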