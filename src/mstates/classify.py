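"""Two-feature (θRP, C) SVM classification with cross-validation.

The classifier is a support vector machine over the two-dimensional
feature space of theta relative power and microstate LZC, standardized
per feature on the training data.  Evaluation follows clinical
convention: stratified k-fold cross-validation with the scaler refit on
each training fold, out-of-fold predictions pooled into one confusion
matrix, and classification rate / sensitivity / specificity reported as
percentages.
"""

from __future__ import annotations

import dataclasses
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .recording import ParameterError

FEATURE_COLUMNS = ("theta_rp", "C")


class ConfigMismatchError(ValueError):
    """Features were computed under a different configuration than the model's."""


def _round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (88.85 -> 88.9, 81.25 -> 81.3)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class ConfusionMetrics:
    """Counts and the derived percentage statistics.

    ``cr``, ``sensitivity`` and ``specificity`` are rounded to one
    decimal half-away-from-zero (reporting convention); the unrounded
    values are available as ``cr_raw`` etc.  A statistic whose
    denominator is zero is ``None`` and listed in ``undefined``.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def cr_raw(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def sensitivity_raw(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity_raw(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def cr(self) -> float:
        return _round1(self.cr_raw)

    @property
    def sensitivity(self) -> float | None:
        raw = self.sensitivity_raw
        return None if raw is None else _round1(raw)

    @property
    def specificity(self) -> float | None:
        raw = self.specificity_raw
        return None if raw is None else _round1(raw)

    @property
    def undefined(self) -> list:
        out = []
        if self.sensitivity_raw is None:
            out.append("sensitivity")
        if self.specificity_raw is None:
            out.append("specificity")
        return out

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "cr": self.cr, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    """Build :class:`ConfusionMetrics`, validating the counts."""
    counts = (tp, fn, tn, fp)
    if any(c < 0 for c in counts):
        raise ParameterError("confusion counts must be nonnegative")
    if sum(counts) == 0:
        raise ParameterError("empty confusion matrix")
    return ConfusionMetrics(tp, fn, tn, fp)


class MicrostateSVC(BaseEstimator, ClassifierMixin):
    """SVM over standardized (θRP, C) features.

    Parameters
    ----------
    kernel : {"rbf", "linear"}
        RBF by default; the decision surface in the 2-D feature plane is
        then a smooth boundary rather than a line.
    C : float
        SVM regularization strength.
    gamma : "median" or float
        RBF bandwidth.  ``"median"`` uses the median heuristic,
        ``gamma = 1 / (2 * median pairwise distance**2)`` on the
        standardized training features.
    """

    def __init__(self, kernel="rbf", C=1.0, gamma="median", random_state=None):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ParameterError("X must be (n, features) matching y")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        gamma = self.gamma
        if self.kernel == "rbf" and gamma == "median":
            d = pdist(Xs)
            d = d[d > 0]
            med = float(np.median(d)) if len(d) else 1.0
            gamma = 1.0 / (2.0 * med**2)
        elif gamma == "median":
            gamma = "scale"
        self.gamma_ = gamma
        self.svm_ = SVC(kernel=self.kernel, C=self.C, gamma=gamma,
                        random_state=self.random_state)
        self.svm_.fit(Xs, y)
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X):
        return self.svm_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))

    def decision_function(self, X):
        return self.svm_.decision_function(
            self.scaler_.transform(np.asarray(X, dtype=float))
        )


def _extract_xy(features: pd.DataFrame, feature_cols, label_col):
    X = features.loc[:, list(feature_cols)].to_numpy(dtype=float)
    y = features[label_col].to_numpy()
    return X, y


def _tally(y_true, y_pred, positive) -> ConfusionMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    return confusion_metrics(tp, fn, tn, fp)


def crossval_svm(
    features: pd.DataFrame,
    folds: int = 10,
    kernel: str = "rbf",
    seed=0,
    positive: str = "AD",
    feature_cols=FEATURE_COLUMNS,
    label_col: str = "group",
    C: float = 1.0,
):
    """Stratified k-fold cross-validation of the (θRP, C) SVM.

    The scaler (and RBF bandwidth) is fit on each training fold only;
    out-of-fold predictions are pooled into a single confusion matrix.
    If a class has fewer members than ``folds`` the data is refolded with
    a warning so every training fold contains both classes.

    Returns ``(ConfusionMetrics, fold_records)``.
    """
    X, y = _extract_xy(features, feature_cols, label_col)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ParameterError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ParameterError("need at least 2 subjects per class")
    n_folds = int(min(folds, counts.min()))
    if n_folds < folds:
        warnings.warn(
            f"refolding from {folds} to {n_folds} folds so each training "
            "fold contains both classes"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_records = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        model = MicrostateSVC(kernel=kernel, C=C, random_state=seed).fit(
            X[train], y[train]
        )
        pred = model.predict(X[test])
        y_pred[test] = pred
        fold_records.append({
            "fold": fold,
            "test_index": test.tolist(),
            "n_correct": int(np.sum(pred == y[test])),
            "n_test": len(test),
        })
    return _tally(y, y_pred, positive), fold_records


def train_svm(features: pd.DataFrame, kernel="rbf", seed=0,
              feature_cols=FEATURE_COLUMNS, label_col="group",
              C: float = 1.0, config_hash: str | None = None) -> MicrostateSVC:
    """Fit the SVM on a full feature table; stamps the feature config hash."""
    X, y = _extract_xy(features, feature_cols, label_col)
    model = MicrostateSVC(kernel=kernel, C=C, random_state=seed).fit(X, y)
    model.config_hash_ = config_hash
    return model


def apply_to_cohort(
    model: MicrostateSVC,
    features: pd.DataFrame,
    positive: str = "AD",
    feature_cols=FEATURE_COLUMNS,
    label_col: str = "group",
    config_hash: str | None = None,
    prediction_map: dict | None = None,
):
    """Predict an independent cohort; metrics when true labels are present.

    If both the model and the call carry a feature-configuration hash and
    they differ, the call is refused: features computed under a different
    configuration (complexity flags, band edges, channel format) are not
    comparable, and the model must be retrained on features in the new
    format instead.

    ``prediction_map`` renames predicted classes before tallying, e.g.
    ``{"AD": "MCIc", "HOA": "MCIs"}`` when an AD-vs-control model is used
    to predict which MCI patients will convert.

    Returns ``(predictions DataFrame, ConfusionMetrics or None)``.
    """
    model_hash = getattr(model, "config_hash_", None)
    if model_hash is not None and config_hash is not None and model_hash != config_hash:
        raise ConfigMismatchError(
            f"model was trained under config {model_hash} but features were "
            f"computed under {config_hash}; recompute features or retrain "
            "the classifier on the new format"
        )
    X = features.loc[:, list(feature_cols)].to_numpy(dtype=float)
    pred = model.predict(X)
    if prediction_map:
        pred = np.array([prediction_map.get(p, p) for p in pred])
    out = pd.DataFrame({
        "subject_id": features.get("subject_id", pd.RangeIndex(len(features))),
        "predicted": pred,
        "decision_value": model.decision_function(X),
    })
    metrics = None
    if label_col in features.columns:
        out["true"] = features[label_col].to_numpy()
        metrics = _tally(out["true"], pred, positive)
    return out, metrics


def plot_decision_regions(model: MicrostateSVC, features: pd.DataFrame,
                          path, feature_cols=FEATURE_COLUMNS,
                          label_col: str = "group") -> None:
    """Render the 2-D decision regions with the cohort overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X, y = _extract_xy(features, feature_cols, label_col)
    pad = 0.1 * (X.max(axis=0) - X.min(axis=0) + 1e-9)
    xs = np.linspace(X[:, 0].min() - pad[0], X[:, 0].max() + pad[0], 300)
    ys = np.linspace(X[:, 1].min() - pad[1], X[:, 1].max() + pad[1], 300)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    zz = model.decision_function(grid).reshape(gx.shape)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(gx, gy, zz > 0, alpha=0.25, cmap="coolwarm")
    for cls, marker in zip(np.unique(y), "ox^s"):
        sel = y == cls
        ax.scatter(X[sel, 0], X[sel, 1], marker=marker, label=str(cls), s=25)
    ax.set_xlabel(feature_cols[0])
    ax.set_ylabel(feature_cols[1])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
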