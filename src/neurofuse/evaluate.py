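"""Classification scoring, ROI importance ranking and cohort statistics.

Confusion-based scores (accuracy, sensitivity, specificity, precision,
recall, F1), ROC/AUC by trapezoidal integration over the swept-threshold
curve, encoder-weight ROI importance (row-wise absolute sums of the first
layer weight matrix) aggregated across cross-validation folds by selection
frequency, and the simple demographics tests (2x2 chi-square, two-sample
t-test from summary statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidArgumentError
from .model import AutoencoderModel

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "ScoreSet",
    "RoiRanking",
    "confusion_counts",
    "classification_scores",
    "roc_auc",
    "rank_rois",
    "aggregate_top_rois",
    "chi_square_2x2",
    "two_sample_ttest",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positives are cases, negatives controls."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidArgumentError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class RocCurve:
    """ROC curve points: x = false-positive rate, y = true-positive rate."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if (np.diff(self.fpr) < 0).any():
            raise InvalidArgumentError("fpr must be non-decreasing")


@dataclass
class ScoreSet:
    """One fold's scores, as fractions in [0, 1]; None where undefined."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "auc",
                "accuracy",
                "sensitivity",
                "specificity",
                "precision",
                "recall",
                "f1",
            )
        }


@dataclass
class RoiRanking:
    """Cross-fold ROI importance summary.

    ``per_fold_top`` holds each fold's ordered top-k ROI ids;
    ``frequency`` counts, per ROI, the folds whose top-k contain it; the
    final ranking keeps the ``k`` most frequently selected ROIs with their
    mean importance expressed as a percentage of the final list's total.
    """

    per_fold_top: list[list[int]]
    frequency: dict[int, int]
    final: list[dict] = field(default_factory=list)  # roi, frequency, weight_pct

    @property
    def final_rois(self) -> list[int]:
        return [entry["roi"] for entry in self.final]


def confusion_counts(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FN/TN/FP; predicted positive iff probability >= threshold."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if len(y_true) != len(y_prob):
        raise InvalidArgumentError("y_true and y_prob lengths differ")
    pred = y_prob >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y_true == 1))),
        fn=int(np.sum(~pred & (y_true == 1))),
        tn=int(np.sum(~pred & (y_true == 0))),
        fp=int(np.sum(pred & (y_true == 0))),
    )


def _safe_ratio(num, den):
    return None if den == 0 else num / den


def classification_scores(c: ConfusionCounts) -> ScoreSet:
    """Confusion-based scores; a zero denominator yields None, not NaN."""
    total = c.tp + c.fn + c.tn + c.fp
    sens = _safe_ratio(c.tp, c.tp + c.fn)
    spec = _safe_ratio(c.tn, c.tn + c.fp)
    prec = _safe_ratio(c.tp, c.tp + c.fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return ScoreSet(
        accuracy=_safe_ratio(c.tp + c.tn, total),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=sens,
        f1=f1,
    )


def roc_auc(y_true, y_prob) -> tuple[RocCurve, float]:
    """ROC curve over swept thresholds and its trapezoidal area.

    The area equals the probability that a random positive scores above a
    random negative, with ties credited 0.5.
    """
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if len(np.unique(y_true)) < 2:
        raise InvalidArgumentError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true, y_prob, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr), auc


def rank_rois(
    ae: AutoencoderModel | np.ndarray, roi_ids=None
) -> list[tuple[int, float]]:
    """Order ROIs by first-layer weight importance.

    Importance of ROI j is the sum of absolute weights along row j of the
    encoder (ROI-rows x latent-columns) matrix.  Descending importance;
    ties break by ROI id ascending.
    """
    w = ae.encoder_w if isinstance(ae, AutoencoderModel) else np.asarray(ae, float)
    importance = np.abs(w).sum(axis=1)
    if roi_ids is None:
        roi_ids = np.arange(1, len(importance) + 1)
    roi_ids = np.asarray(roi_ids)
    order = np.lexsort((roi_ids, -importance))
    return [(int(roi_ids[i]), float(importance[i])) for i in order]


def aggregate_top_rois(
    per_fold_rankings: list[list[tuple[int, float]]],
    k: int = 10,
) -> RoiRanking:
    """Aggregate per-fold rankings into a final top-k list.

    Selection frequency is the number of folds whose top-k contains the
    ROI; the final list keeps the k highest-frequency ROIs (ties broken by
    mean importance, then ROI id) and reports each ROI's mean importance as
    a percentage of the final list's summed importance.
    """
    if not per_fold_rankings:
        raise InvalidArgumentError("need at least one fold ranking")
    per_fold_top = [[roi for roi, _ in ranking[:k]] for ranking in per_fold_rankings]
    freq: dict[int, int] = {}
    imp_sum: dict[int, list[float]] = {}
    for ranking, top in zip(per_fold_rankings, per_fold_top):
        for roi, imp in ranking:
            imp_sum.setdefault(roi, []).append(imp)
        for roi in top:
            freq[roi] = freq.get(roi, 0) + 1
    mean_imp = {roi: float(np.mean(v)) for roi, v in imp_sum.items()}
    candidates = sorted(
        freq, key=lambda roi: (-freq[roi], -mean_imp[roi], roi)
    )[:k]
    total = sum(mean_imp[roi] for roi in candidates)
    final = [
        {
            "roi": roi,
            "frequency": freq[roi],
            "mean_importance": mean_imp[roi],
            "weight_pct": 100.0 * mean_imp[roi] / total if total > 0 else 0.0,
        }
        for roi in candidates
    ]
    return RoiRanking(per_fold_top=per_fold_top, frequency=freq, final=final)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise InvalidArgumentError("counts must form a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InvalidArgumentError("zero marginal in contingency table")
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise InvalidArgumentError("expected counts must be positive")
    return float(stat), float(p)


def two_sample_ttest(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise InvalidArgumentError("standard deviations must be non-negative")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    return float(res.statistic), float(res.pvalue)
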