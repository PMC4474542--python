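"""SVM classification of regulatory vs background regions, with
information-gain feature ranking.

The classifier is a polynomial-kernel SVM (degree 2, misclassification cost
C = 10) evaluated by stratified 10-fold cross-validation on a balanced
positive/background set. Performance is the area under the ROC curve of the
pooled held-out decision scores (per-fold AUCs are also kept). Feature
importance is the information gain

    IG(S, F) = H(S) - sum_v |S_v|/|S| H(S_v),   H(S) = -sum_i p_i log2 p_i

after equal-frequency discretisation of continuous features.

The model/results pair (:class:`RegulatoryRegionModel` /
:class:`RegulatoryRegionResults`) wraps these pieces in a fit-and-summarise
interface over a feature table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FEATURE_NAMES, ValidationError

DEFAULT_FOLDS = 10
DEFAULT_DEGREE = 2
DEFAULT_COST = 10.0
DEFAULT_COEF0 = 1.0
DEFAULT_BINS = 10


def entropy(labels) -> float:
    """Shannon entropy of a label assignment, in bits (0 log 0 := 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def discretize(values, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency bin assignments via quantile cut-points.

    Ties at a cut-point go to the lower bin; a constant vector collapses to
    a single bin.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("discretize expects a 1-D vector")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    # count of edges strictly below each value -> value == edge falls low
    return np.searchsorted(edges, values, side="left")


def information_gain(feature_values, labels, n_bins: int = DEFAULT_BINS) -> float:
    """Entropy reduction of the labels given the discretised feature, in bits."""
    feature_values = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels)
    if len(feature_values) != len(labels):
        raise ValidationError("feature and label vectors differ in length")
    bins = discretize(feature_values, n_bins)
    h = entropy(labels)
    n = len(labels)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.sum() / n * entropy(labels[mask])
    return h - cond


def rank_features(
    frame: pd.DataFrame, labels, feature_names=FEATURE_NAMES, n_bins: int = DEFAULT_BINS
) -> pd.Series:
    """Information gain per feature, sorted descending."""
    if len(feature_names) < 2:
        raise ValidationError("rank_features expects >= 2 features")
    ig = {name: information_gain(frame[name].to_numpy(), labels, n_bins) for name in feature_names}
    return pd.Series(ig).sort_values(ascending=False)


@dataclass(slots=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores, labels) -> RocCurve:
    """ROC points and AUC; labels are 1/positive vs 0/background.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random background (ties counted half).
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = metrics.roc_curve(y, scores)
    return RocCurve(fpr, tpr, float(metrics.roc_auc_score(y, scores)))


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "SOU":
        return (labels == "positive").astype(int)
    return labels.astype(int)


@dataclass(slots=True)
class CVResult:
    """Held-out decision scores and derived metrics of one CV run."""

    scores: np.ndarray
    y: np.ndarray
    fold_of: np.ndarray
    roc: RocCurve
    fold_aucs: list[float]
    config: dict

    @property
    def auc(self) -> float:
        return self.roc.auc


def cross_validate(
    X,
    labels,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    kernel_degree: int = DEFAULT_DEGREE,
    cost: float = DEFAULT_COST,
    coef0: float = DEFAULT_COEF0,
    feature_names=FEATURE_NAMES,
    feature_subset=None,
    motif_refit=None,
    motif_feature: str = "motif_score",
) -> CVResult:
    """Stratified k-fold SVM cross-validation.

    Features are standardised with training-fold statistics only. When
    ``motif_refit`` is given (callable train_idx -> per-sample motif scores),
    the motif column is recomputed inside each fold from its training
    regions, so held-out regions never contribute to the enrichment table
    they are scored against.
    """
    X = pd.DataFrame(X, columns=feature_names) if not isinstance(X, pd.DataFrame) else X.copy()
    y = _binary_labels(labels)
    names = list(feature_subset) if feature_subset is not None else list(feature_names)
    unknown = [n for n in names if n not in X.columns]
    if unknown:
        raise ValidationError(f"unknown features {unknown}")
    counts = Counter(y)
    if min(counts.values(), default=0) < folds:
        raise ValidationError(f"need >= {folds} samples per class for {folds}-fold CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    fold_aucs: list[float] = []

    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        Xf = X.copy()
        if motif_refit is not None and motif_feature in names:
            Xf[motif_feature] = motif_refit(train_idx)
        mat = Xf[names].to_numpy(dtype=float)
        scaler = StandardScaler().fit(mat[train_idx])
        svm = SVC(kernel="poly", degree=kernel_degree, C=cost, coef0=coef0)
        svm.fit(scaler.transform(mat[train_idx]), y[train_idx])
        s = svm.decision_function(scaler.transform(mat[test_idx]))
        scores[test_idx] = s
        fold_of[test_idx] = fold
        fold_aucs.append(float(metrics.roc_auc_score(y[test_idx], s)))

    roc = roc_auc(scores, y)
    config = {
        "folds": folds,
        "seed": seed,
        "kernel_degree": kernel_degree,
        "cost": cost,
        "coef0": coef0,
        "features": names,
    }
    return CVResult(scores, y, fold_of, roc, fold_aucs, config)


class RegulatoryRegionModel:
    """Regulatory-region classifier over a per-region feature table.

    Parameters
    ----------
    feature_table : DataFrame
        One row per region with the five feature columns and a ``label``
        column ('positive'/'background'). :func:`methylreg.io.feature_frame`
        produces this layout.
    motif_refit : callable, optional
        ``train_idx -> motif score column`` for leakage-free per-fold motif
        tables (see :class:`methylreg.motifs.FoldAwareMotifScorer`).
    """

    def __init__(self, feature_table: pd.DataFrame, feature_names=FEATURE_NAMES, motif_refit=None):
        missing = [c for c in (*feature_names, "label") if c not in feature_table.columns]
        if missing:
            raise ValidationError(f"feature table lacks columns {missing}")
        self.data = feature_table.reset_index(drop=True)
        self.feature_names = tuple(feature_names)
        self.motif_refit = motif_refit

    @classmethod
    def from_feature_table(cls, frame: pd.DataFrame, **kwargs) -> "RegulatoryRegionModel":
        return cls(frame, **kwargs)

    def fit(
        self,
        folds: int = DEFAULT_FOLDS,
        seed: int = 0,
        kernel_degree: int = DEFAULT_DEGREE,
        cost: float = DEFAULT_COST,
        coef0: float = DEFAULT_COEF0,
        feature_subset=None,
        n_bins: int = DEFAULT_BINS,
    ) -> "RegulatoryRegionResults":
        cv = cross_validate(
            self.data,
            self.data["label"].to_numpy(),
            folds=folds,
            seed=seed,
            kernel_degree=kernel_degree,
            cost=cost,
            coef0=coef0,
            feature_names=self.feature_names,
            feature_subset=feature_subset,
            motif_refit=self.motif_refit,
        )
        ig = rank_features(
            self.data, self.data["label"].to_numpy(), feature_names=self.feature_names, n_bins=n_bins
        )
        return RegulatoryRegionResults(model=self, cv=cv, information_gain=ig)


@dataclass
class RegulatoryRegionResults:
    """Cross-validated performance and feature ranking of a fitted model."""

    model: RegulatoryRegionModel
    cv: CVResult
    information_gain: pd.Series

    @property
    def auc(self) -> float:
        return self.cv.auc

    @property
    def fold_aucs(self) -> list[float]:
        return self.cv.fold_aucs

    @property
    def roc(self) -> RocCurve:
        return self.cv.roc

    def summary(self) -> str:
        cfg = self.cv.config
        lines = [
            "Regulatory region classification (SVM, polynomial kernel)",
            "=" * 58,
            f"regions: {len(self.cv.y)}  (positives {int(self.cv.y.sum())}, "
            f"backgrounds {int((1 - self.cv.y).sum())})",
            f"kernel degree: {cfg['kernel_degree']}   C: {cfg['cost']}   "
            f"folds: {cfg['folds']}   seed: {cfg['seed']}",
            f"features: {', '.join(cfg['features'])}",
            "-" * 58,
            f"AUC (pooled held-out scores): {self.auc:.3f}",
            f"AUC per fold: mean {np.mean(self.fold_aucs):.3f} "
            f"(min {min(self.fold_aucs):.3f}, max {max(self.fold_aucs):.3f})",
            "-" * 58,
            "information gain (bits):",
        ]
        for name, val in self.information_gain.items():
            lines.append(f"  {name:<15s} {val:.3f}")
        return "\n".join(lines)
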