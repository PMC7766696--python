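"""Cross-validation protocol and classification metrics.

Sixfold cross-validation with class-stratified folds: each training
union of five folds is cleaned (negatives undersampled by the kNN
treatment), the linear SVM is fit on the cleaned set, and the *entire*
held-out fold — untouched by cleaning — is scored.  Sensitivity,
specificity, precision, accuracy and the Matthews correlation
coefficient are computed per fold and averaged; decision scores are
pooled across folds for a single ROC curve and AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .alphabet import RESIDUE_ORDER
from .cleaning import CleaningConfig, clean_training_set
from .model import ModelConfig, train
from .ram import encode_dataset
from .sequence_io import Dataset

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
        )


@dataclass
class MetricsReport:
    """The five confusion-derived metrics, with undefined-ratio flags.

    A metric whose denominator is zero is reported as 0.0 and named in
    ``undefined`` (never silently NaN).
    """

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    undefined: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision, accuracy and MCC from counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); accuracy = (TN+TP)/(FN+FP+TN+TP);
    MCC = (TN*TP - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("all confusion counts are zero")
    undefined = set()

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    accuracy = (tn + tp) / total
    mcc_den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        undefined.add("mcc")
        mcc = 0.0
    else:
        mcc = (tn * tp - fn * fp) / np.sqrt(mcc_den)
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        accuracy=accuracy,
        mcc=mcc,
        undefined=frozenset(undefined),
    )


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """ROC curve points and area under the curve for pooled scores.

    The trapezoidal area over the empirical ROC equals the tie-corrected
    Mann-Whitney rank statistic P(score+ > score-) + P(tie)/2.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr), float(_trapezoid_auc(fpr, tpr))


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    removed_indices: np.ndarray  # cleaned-away negatives, dataset index space
    cleaning_N: int
    achieved_ratio: float
    counts: ConfusionCounts
    metrics: MetricsReport
    auc: Optional[float]


@dataclass
class CVReport:
    folds: list[FoldResult]
    mean_metrics: dict[str, float]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    roc: RocCurve
    auc: float
    seed: int
    n_folds: int
    excluded: dict[str, list[int]] = field(default_factory=dict)

    def fold_aucs(self) -> list[Optional[float]]:
        return [f.auc for f in self.folds]

    def summary_lines(self) -> list[str]:
        lines = [
            f"{'metric':<12} {'mean over folds':>16}",
        ]
        for name in METRIC_NAMES:
            lines.append(f"{name:<12} {self.mean_metrics[name]:>16.4f}")
        lines.append(f"{'auc (pooled)':<12} {self.auc:>16.4f}")
        return lines


def _average_fold_metrics(
    fold_results: Sequence[FoldResult],
) -> tuple[dict[str, float], dict[str, list[int]]]:
    means: dict[str, float] = {}
    excluded: dict[str, list[int]] = {}
    for name in METRIC_NAMES:
        vals, skipped = [], []
        for fr in fold_results:
            if name in fr.metrics.undefined:
                skipped.append(fr.fold)
            else:
                vals.append(getattr(fr.metrics, name))
        if skipped:
            excluded[name] = skipped
            warnings.warn(
                f"{name} undefined in folds {skipped}; excluded from average"
            )
        means[name] = float(np.mean(vals)) if vals else 0.0
    return means, excluded


def cross_validate_features(
    table,
    labels,
    cleaning_config: Optional[CleaningConfig] = None,
    model_config: Optional[ModelConfig] = None,
    folds: int = 6,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV on an encoded feature table.

    Cleaning is recomputed inside each fold's training union and never
    touches the held-out fold; every site is scored exactly once.
    """
    cleaning_config = cleaning_config or CleaningConfig()
    model_config = model_config or ModelConfig()
    X = np.asarray(getattr(table, "X", table), dtype=float)
    schema = getattr(table, "schema", None)
    y = np.asarray(labels, dtype=int)

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_scores = np.full(len(y), np.nan)
    fold_results: list[FoldResult] = []
    for k, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        N_used, cleaned = clean_training_set(X[train_idx], y[train_idx], cleaning_config)
        removed_global = train_idx[cleaned.removed_indices]
        # leakage guard: cleaning must never reach into the held-out fold
        assert not set(removed_global) & set(test_idx)
        keep = train_idx[cleaned.retained_indices]
        model = train(X[keep], y[keep], model_config)
        scores = model.decision_scores(X[test_idx])
        preds = (scores > 0).astype(int)
        pooled_scores[test_idx] = scores
        counts = ConfusionCounts.from_labels(y[test_idx], preds)
        metrics = compute_metrics(counts)
        fold_auc = None
        if len(np.unique(y[test_idx])) == 2:
            _, fold_auc = roc_auc(scores, y[test_idx])
        logger.info(
            "fold %d: N=%d removed=%d ratio=%.2f sens=%.3f acc=%.3f",
            k, N_used, len(removed_global), cleaned.achieved_ratio,
            metrics.sensitivity, metrics.accuracy,
        )
        fold_results.append(
            FoldResult(
                fold=k,
                test_indices=test_idx,
                removed_indices=removed_global,
                cleaning_N=N_used,
                achieved_ratio=cleaned.achieved_ratio,
                counts=counts,
                metrics=metrics,
                auc=fold_auc,
            )
        )

    assert not np.any(np.isnan(pooled_scores)), "every site must be scored once"
    curve, pooled_auc = roc_auc(pooled_scores, y)
    means, excluded = _average_fold_metrics(fold_results)
    return CVReport(
        folds=fold_results,
        mean_metrics=means,
        pooled_scores=pooled_scores,
        pooled_labels=y,
        roc=curve,
        auc=pooled_auc,
        seed=seed,
        n_folds=folds,
        excluded=excluded,
    )


def run_cross_validation(
    dataset: Dataset,
    n: int = 6,
    retained: Sequence[str] = RESIDUE_ORDER,
    cleaning_config: Optional[CleaningConfig] = None,
    model_config: Optional[ModelConfig] = None,
    folds: int = 6,
    seed: int = 0,
) -> CVReport:
    """Encode a dataset and evaluate it under the k-fold protocol."""
    table, labels = encode_dataset(dataset, n=n, retained=retained)
    return cross_validate_features(
        table,
        labels,
        cleaning_config=cleaning_config,
        model_config=model_config,
        folds=folds,
        seed=seed,
    )
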