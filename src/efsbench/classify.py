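"""Linear discriminant wrapper classifier and balanced-accuracy evaluation.

The whole benchmark scores candidate feature subsets with one simple
model: a two-class linear discriminant whose decision is a thresholded
weighted sum of the features, ``y = 1  iff  omega . x > S``. The weight
magnitude |omega_j| of a fitted model serves as the relative importance
of feature j, which is what the eliminative selectors consume.

Features are standardized internally before the discriminant solve, so
fitted predictions are exactly invariant to affine rescaling of any
feature column and the importance ordering is unit-free. When the pooled
within-class covariance is rank deficient the solve falls back to a
pseudo-inverse; when d >= n a Ledoit-Wolf shrinkage estimate is used
instead, so collinear or duplicated features never abort a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import pinvh
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold

from .catalog_io import DegenerateLabelError, FeatureTable

__all__ = [
    "LinearDiscriminantModel",
    "CVScheme",
    "fit_lda",
    "predict",
    "balanced_accuracy",
    "cv_bacc",
    "feature_importance",
]


@dataclass
class LinearDiscriminantModel:
    """Fitted linear discriminant: predict 1 iff weights . x > threshold."""

    weights: np.ndarray
    threshold: float
    feature_names: list[str]
    class_priors: tuple[float, float] = (0.5, 0.5)
    # per-column scale used during fitting; ones for hand-built models
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weights and feature_names length mismatch")
        if self.scale is None:
            self.scale = np.ones_like(self.weights)


def _as_matrix(table: FeatureTable | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, FeatureTable):
        return table.values, table.feature_names
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_lda(table: FeatureTable | np.ndarray, y) -> LinearDiscriminantModel:
    """Fit the two-class linear discriminant.

    Solves Sigma_pooled w = (mu1 - mu0) on standardized columns; the
    threshold is the standard prior-adjusted midpoint cut on the
    discriminant score, mapped back to the raw feature scale.
    """
    X, names = _as_matrix(table)
    y = np.asarray(y, dtype=int).ravel()
    n, d = X.shape
    if y.shape[0] != n:
        raise ValueError("label length does not match table rows")
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelError("fit_lda requires exactly two classes")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Z = (X - mean) / std

    m0 = y == classes[0]
    m1 = ~m0
    n0, n1 = int(m0.sum()), int(m1.sum())
    mu0 = Z[m0].mean(axis=0)
    mu1 = Z[m1].mean(axis=0)
    Z0 = Z[m0] - mu0
    Z1 = Z[m1] - mu1
    pooled = (Z0.T @ Z0 + Z1.T @ Z1) / max(n - 2, 1)

    if d >= n:
        shrunk, _ = ledoit_wolf(np.vstack([Z0, Z1]), assume_centered=True)
        w_z = np.linalg.solve(shrunk + 1e-12 * np.eye(d), mu1 - mu0)
    else:
        # pinvh gives the minimum-norm solution for exactly collinear columns
        w_z = pinvh(pooled, atol=1e-10) @ (mu1 - mu0)

    pri0, pri1 = n0 / n, n1 / n
    s_z = float(w_z @ (mu0 + mu1) / 2.0 + np.log(pri0 / pri1))
    weights = w_z / std
    threshold = s_z + float(weights @ mean)
    model = LinearDiscriminantModel(
        weights, threshold, names, (pri0, pri1), scale=std.copy()
    )
    model._classes = (int(classes[0]), int(classes[1]))  # type: ignore[attr-defined]
    return model


def predict(model: LinearDiscriminantModel, table: FeatureTable | np.ndarray) -> np.ndarray:
    """Apply the decision rule: 1 where omega . x > S, else 0."""
    X, _ = _as_matrix(table)
    return (X @ model.weights > model.threshold).astype(int)


def balanced_accuracy(y_true, y_pred) -> float:
    """(sensitivity + specificity) / 2; 0.5 for any constant predictor."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    if classes.size != 2:
        raise DegenerateLabelError("balanced accuracy undefined for one class")
    pos, neg = classes[1], classes[0]
    sens = np.mean(y_pred[y_true == pos] == pos)
    spec = np.mean(y_pred[y_true == neg] == neg)
    return float((sens + spec) / 2.0)


@dataclass
class CVScheme:
    """Stratified k-fold scheme; seeded shuffling makes folds reproducible."""

    k: int = 5
    stratified: bool = True
    seed: int = 0

    def splits(self, y: np.ndarray):
        skf = StratifiedKFold(
            n_splits=self.k, shuffle=True, random_state=self.seed
        )
        return skf.split(np.zeros(len(y)), y)


@dataclass
class CVResult:
    mean: float
    sd: float
    per_fold: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __iter__(self):
        return iter((self.mean, self.sd, self.per_fold))


def cv_bacc(table: FeatureTable | np.ndarray, y, scheme: CVScheme) -> CVResult:
    """Held-out balanced accuracy per stratified fold; mean and population sd.

    Raises if stratification cannot place both classes in every fold.
    """
    X, _ = _as_matrix(table)
    y = np.asarray(y, dtype=int).ravel()
    per_fold = []
    for train, test in scheme.splits(y):
        if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
            raise DegenerateLabelError("a CV fold is missing a class")
        model = fit_lda(X[train], y[train])
        per_fold.append(balanced_accuracy(y[test], predict(model, X[test])))
    per_fold = np.asarray(per_fold)
    return CVResult(float(per_fold.mean()), float(per_fold.std()), per_fold)


def feature_importance(model: LinearDiscriminantModel) -> np.ndarray:
    """Relative importance |omega_j| on the model's fitting scale.

    For fitted models the stored per-column scale converts raw-space
    weights back to the standardized magnitudes they were solved in, so
    the ordering does not depend on feature units; for directly
    constructed models (scale of ones) this is plain |omega_j|.
    """
    return np.abs(model.weights) * model.scale


def resubstitution_bacc(table: FeatureTable | np.ndarray, y) -> float:
    model = fit_lda(table, y)
    return balanced_accuracy(y, predict(model, table))
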