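"""Kernel-SVM swallow detection with calibrated posterior probabilities.

The first detection tier classifies each breathing cycle from its
11-feature vector. A kernel SVM provides the signed decision value

    D(x) = sum_k y_k a_k K(x_k, x) + b,

positive for cycles with swallows (label +1) and negative for normal
breathing (label −1); |D(x)| grows with the distance D(x)/C to the
maximum-margin boundary and hence with classification confidence. For
the HMM refinement tier the decision value is mapped to a posterior
probability through a two-parameter sigmoid

    prob(y = 1 | x) = 1 / (1 + exp(A·D(x) + B)),

with (A, B) estimated by minimizing the negative log likelihood of a
calibration set (A < 0 so the posterior increases with D). Calibration
uses out-of-fold decision values from an internal split of the training
set so the sigmoid never sees decision values of points the SVM was
trained on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import rbf_kernel, linear_kernel
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PlattParams",
    "SwallowSVM",
    "kernel_decision",
    "fit_sigmoid",
    "sigmoid_posterior",
    "sigmoid_nll",
]


@dataclass
class PlattParams:
    """Sigmoid constants of the posterior map (named to avoid collision
    with the HMM's A and B matrices)."""

    sigmoid_a: float
    sigmoid_b: float

    def __post_init__(self) -> None:
        if not self.sigmoid_a < 0:
            raise ValueError("sigmoid_a must be negative for the posterior "
                             "to increase with the decision value")


def kernel_decision(x: np.ndarray, support_vectors: np.ndarray,
                    dual_coef: np.ndarray, bias: float,
                    kernel: str = "rbf", gamma: float = 1.0) -> np.ndarray:
    """Evaluate D(x) = Σ_k (y_k a_k) K(x_k, x) + b directly.

    ``dual_coef`` holds the signed products y_k a_k for the stored
    support vectors. Kept as a standalone function so tiny hand-set
    models can be evaluated against pencil-and-paper arithmetic.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    sv = np.atleast_2d(np.asarray(support_vectors, dtype=float))
    if X.shape[1] != sv.shape[1]:
        raise ValueError(f"feature dimension mismatch: {X.shape[1]} != {sv.shape[1]}")
    if kernel == "rbf":
        K = rbf_kernel(sv, X, gamma=gamma)
    elif kernel == "linear":
        K = linear_kernel(sv, X)
    else:
        raise ValueError(f"unsupported kernel {kernel!r}")
    return np.asarray(dual_coef, dtype=float).ravel() @ K + bias


def sigmoid_posterior(d: np.ndarray, params: PlattParams) -> np.ndarray:
    """prob(y = 1 | x) = 1 / (1 + exp(A·D + B)), computed stably."""
    z = params.sigmoid_a * np.asarray(d, dtype=float) + params.sigmoid_b
    return np.exp(-np.logaddexp(0.0, z))


def sigmoid_nll(d: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Negative log likelihood of labels y ∈ {−1, +1} under the sigmoid."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y)
    z = a * d + b
    pos = y == 1
    # -log p(1|x) = logaddexp(0, z);  -log p(-1|x) = logaddexp(0, -z)
    return float(np.logaddexp(0.0, z[pos]).sum() + np.logaddexp(0.0, -z[~pos]).sum())


def fit_sigmoid(decision_values: np.ndarray, labels: np.ndarray,
                tol: float = 1e-8, max_iter: int = 500) -> PlattParams:
    """Fit (A, B) by minimizing the negative log likelihood.

    Uses damped Newton iterations on the two-parameter logistic
    likelihood (convex in (A, B)); convergence is declared when the
    parameter update falls below ``tol``.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError("labels must contain both classes, coded as -1 and +1")

    t = (y == 1).astype(float)  # target = prob of class +1
    theta = np.array([-1.0, 0.0])
    converged = False
    for _ in range(max_iter):
        z = theta[0] * d + theta[1]
        p = np.exp(-np.logaddexp(0.0, z))  # prob(+1)
        # p = sigma(-z), so dNLL/dz_i = t_i - p_i  with z = A d + B
        g_z = t - p
        grad = np.array([(g_z * d).sum(), g_z.sum()])
        w = np.maximum(p * (1 - p), 1e-12)
        H = np.array([[float((w * d * d).sum()), float((w * d).sum())],
                      [float((w * d).sum()), float(w.sum())]])
        H[0, 0] += 1e-10
        H[1, 1] += 1e-10
        step = np.linalg.solve(H, grad)
        # backtracking to keep NLL non-increasing
        nll0 = sigmoid_nll(d, y, *theta)
        if nll0 < 1e-6:
            # separable calibration data: the plain-NLL minimum is at an
            # unbounded slope; the current fit is already (numerically)
            # perfect, so stop here
            converged = True
            break
        scale = 1.0
        for _bt in range(40):
            cand = theta - scale * step
            if sigmoid_nll(d, y, *cand) <= nll0 + 1e-12:
                break
            scale *= 0.5
        theta = theta - scale * step
        if scale == 1.0 and np.abs(step).max() < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            "sigmoid fit did not converge: "
            f"last update {np.abs(scale * step).max():.3g}, "
            f"NLL {sigmoid_nll(d, y, *theta):.6g}")
    if theta[0] >= 0:
        # decision values anti-correlated with labels; refuse silently
        # miscalibrated posteriors
        raise RuntimeError("fitted sigmoid slope is non-negative; decision "
                           "values do not separate the classes in the "
                           "expected direction")
    return PlattParams(float(theta[0]), float(theta[1]))


DEFAULT_PARAM_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale"]}


class SwallowSVM(BaseEstimator, ClassifierMixin):
    """Posterior-probability kernel SVM over per-cycle features.

    Parameters
    ----------
    kernel : {"rbf", "linear"}
        Kernel of the decision function.
    C, gamma :
        SVM hyperparameters, used directly when ``param_grid`` is None.
    param_grid : dict or None
        When given, hyperparameters are chosen by stratified
        cross-validated grid search on the training folds only.
    calibration_folds : int
        Folds of the internal split producing out-of-fold decision
        values for the sigmoid fit.
    posterior_threshold : float
        Pth applied by :meth:`predict`: a cycle is classified as a
        swallow iff its posterior is >= Pth (the boundary posterior
        counts as a swallow).
    class_weight :
        Passed to the underlying SVM; "balanced" counteracts the strong
        normal/swallow imbalance of meal recordings.

    Attributes (after fit)
    ----------------------
    support_vectors_ : ndarray, standardized stored support vectors x_k
    dual_coef_ : ndarray, signed products y_k a_k
    intercept_ : float, bias b
    platt_ : PlattParams, fitted sigmoid constants
    margin_scale_ : float, the positive constant C of the distance
        interpretation D(x)/C (the feature-space norm of the weight
        vector); diagnostic only
    """

    def __init__(self, kernel: str = "rbf", C: float = 10.0, gamma="scale",
                 param_grid: dict | None = None, cv: int = 3,
                 calibration_folds: int = 3, posterior_threshold: float = 0.5,
                 class_weight="balanced", random_state: int | None = 0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.param_grid = param_grid
        self.cv = cv
        self.calibration_folds = calibration_folds
        self.posterior_threshold = posterior_threshold
        self.class_weight = class_weight
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "SwallowSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if set(np.unique(y)) <= {0, 1}:
            y = np.where(y == 1, 1, -1)  # accept 0/1 coding
        if not np.array_equal(np.unique(y), [-1, 1]):
            raise ValueError("training labels must contain both classes "
                             "(+1 swallow, -1 normal)")
        if not 0 <= self.posterior_threshold <= 1:
            raise ValueError("posterior_threshold must be in [0, 1]")

        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)

        if self.param_grid is not None:
            search = GridSearchCV(
                SVC(kernel=self.kernel, class_weight=self.class_weight),
                self.param_grid,
                cv=StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state),
                scoring="f1",
            )
            search.fit(Xs, y)
            params = search.best_params_
        else:
            params = {"C": self.C}
            if self.kernel == "rbf":
                params["gamma"] = self.gamma
        self.svm_params_ = params

        svc = SVC(kernel=self.kernel, class_weight=self.class_weight, **params)
        svc.fit(Xs, y)
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.gamma_ = float(svc._gamma) if self.kernel == "rbf" else None
        self.classes_ = np.array([-1, 1])

        # margin-scale constant of the distance interpretation D(x)/C
        if self.kernel == "rbf":
            K_ss = rbf_kernel(self.support_vectors_, self.support_vectors_,
                              gamma=self.gamma_)
        else:
            K_ss = linear_kernel(self.support_vectors_, self.support_vectors_)
        self.margin_scale_ = float(np.sqrt(max(self.dual_coef_ @ K_ss @ self.dual_coef_, 0.0)))

        # out-of-fold decision values for sigmoid calibration
        d_oof = np.full(len(y), np.nan)
        skf = StratifiedKFold(self.calibration_folds, shuffle=True,
                              random_state=self.random_state)
        for tr, va in skf.split(Xs, y):
            fold = SVC(kernel=self.kernel, class_weight=self.class_weight, **params)
            fold.fit(Xs[tr], y[tr])
            d_oof[va] = fold.decision_function(Xs[va])
        self.platt_ = fit_sigmoid(d_oof, y)
        self.oof_decision_ = d_oof  # fold-clean decisions, aligned to rows of X
        self._sklearn_svc_ = svc  # kept for oracle cross-checks
        return self

    def oof_posterior(self) -> np.ndarray:
        """Out-of-fold training posteriors (sigmoid of the fold-clean
        decision values); the unbiased choice for estimating downstream
        observation statistics such as the HMM emission matrix."""
        check_is_fitted(self, "oof_decision_")
        return sigmoid_posterior(self.oof_decision_, self.platt_)

    # -- inference ---------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Signed decision values D(x), evaluated from the stored kernel
        expansion."""
        check_is_fitted(self, "support_vectors_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors_.shape[1]:
            raise ValueError(
                f"expected {self.support_vectors_.shape[1]} features, got {X.shape[1]}")
        Xs = self.scaler_.transform(X)
        return kernel_decision(Xs, self.support_vectors_, self.dual_coef_,
                               self.intercept_, kernel=self.kernel,
                               gamma=self.gamma_ if self.kernel == "rbf" else 1.0)

    def predict_proba(self, X) -> np.ndarray:
        """Columns [prob(normal), prob(swallow)]; rows sum to 1."""
        check_is_fitted(self, "platt_")
        p1 = sigmoid_posterior(self.decision_function(X), self.platt_)
        return np.column_stack([1.0 - p1, p1])

    def posterior(self, X) -> np.ndarray:
        """prob(y = +1 | x) for each row of X."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, posterior_threshold: float | None = None) -> np.ndarray:
        """Labels in {−1, +1}: swallow iff posterior >= Pth."""
        pth = self.posterior_threshold if posterior_threshold is None else posterior_threshold
        if not 0 <= pth <= 1:
            raise ValueError("posterior_threshold must be in [0, 1]")
        return np.where(self.posterior(X) >= pth, 1, -1)

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        check_is_fitted(self, "platt_")
        blob = {
            "kernel": self.kernel,
            "gamma": self.gamma_,
            "svm_params": {k: (v if not isinstance(v, np.generic) else v.item())
                           for k, v in self.svm_params_.items()},
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "sigmoid_a": self.platt_.sigmoid_a,
            "sigmoid_b": self.platt_.sigmoid_b,
            "margin_scale": self.margin_scale_,
            "posterior_threshold": self.posterior_threshold,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(blob, fh)
        return blob

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SwallowSVM":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        model = cls(kernel=source["kernel"],
                    posterior_threshold=source.get("posterior_threshold", 0.5))
        model.support_vectors_ = np.asarray(source["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(source["dual_coef"], dtype=float)
        model.intercept_ = float(source["intercept"])
        model.gamma_ = source["gamma"]
        model.svm_params_ = source.get("svm_params", {})
        model.margin_scale_ = float(source.get("margin_scale", 0.0))
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(source["scaler_mean"], dtype=float)
        scaler.scale_ = np.asarray(source["scaler_scale"], dtype=float)
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(scaler.mean_)
        model.scaler_ = scaler
        model.platt_ = PlattParams(float(source["sigmoid_a"]), float(source["sigmoid_b"]))
        model.classes_ = np.array([-1, 1])
        return model
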