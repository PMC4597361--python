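"""Classification reliability metrics and survival analysis.

Sensitivity and specificity are evaluated at a fixed operating point
(decision value strictly greater than the threshold predicts the positive
class). The ROC curve is the polygonal line traced as the threshold sweeps
from +inf down to -inf, with one vertex per distinct score; AUC is the area
between that polygon and the X-axis, accumulated over the rectangle (and,
for tied scores, trapezoid) decomposition — numerically identical to the
normalized Mann-Whitney U statistic. Kaplan-Meier estimation and the
log-rank test are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, DegenerateGroupError, ValidationError


class DatasetMetrics(NamedTuple):
    """AUC plus fixed-threshold sensitivity/specificity on one dataset."""

    auc: float
    sensitivity: float
    specificity: float


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class RocCurve:
    """Polygonal ROC: vertices (fpr, tpr) with the score threshold at each vertex.

    Starts at (0, 0) with threshold +inf; both coordinates are non-decreasing
    and the last vertex is (1, 1).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    if not np.isfinite(scores).all():
        raise ValidationError("non-finite score")
    y = labels.astype(np.int64)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateCohortError("both outcome classes required")
    return scores, y


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix predicting positive iff score > threshold."""
    scores, y = _check_scores_labels(scores, labels)
    pred = scores > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(tp/(tp+fn), tn/(tn+fp)) as fractions in [0, 1]."""
    if counts.n_positives == 0 or counts.n_negatives == 0:
        raise DegenerateCohortError("sensitivity/specificity need both classes")
    return counts.tp / counts.n_positives, counts.tn / counts.n_negatives


def as_percent(fraction: float, ndigits: int = 1) -> float:
    """Report a fraction as a percentage rounded to one decimal by default."""
    return round(100.0 * fraction, ndigits)


def _roc_points(scores: np.ndarray, y: np.ndarray):
    """Cumulative (fps, tps) at each distinct score, descending threshold."""
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    distinct = np.r_[ss[1:] != ss[:-1], True]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(1 - ys)[distinct]
    return fps, tps, ss[distinct]


def roc_curve(scores, labels) -> RocCurve:
    """ROC polygon from the threshold sweep; tied scores move diagonally."""
    scores, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    fps, tps, thr = _roc_points(scores, y)
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thresholds = np.r_[np.inf, thr]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(scores, labels) -> float:
    """Area under the polygonal ROC curve.

    Computed as the rectangle/trapezoid decomposition of the polygon; equals
    (correctly ordered positive-negative pairs + half the tied pairs) /
    (n_pos * n_neg).
    """
    scores, y = _check_scores_labels(scores, labels)
    return _auc_core(scores, y)


def _auc_core(scores: np.ndarray, y: np.ndarray) -> float:
    """Polygon-area AUC for pre-validated float scores / 0-1 int labels."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    fps, tps, _ = _roc_points(scores, y)
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    return float(np.trapezoid(tpr, fpr))


def score_metrics(scores: np.ndarray, y: np.ndarray, threshold: float) -> DatasetMetrics:
    """AUC + sensitivity/specificity at the fixed operating point (score > threshold).

    Minimal-overhead path shared by the public metric operations and the
    exhaustive search; ``scores``/``y`` must already be aligned numpy arrays
    with both classes present.
    """
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    pred = scores > threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return DatasetMetrics(
        auc=_auc_core(scores, y),
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
    )


# ---------------------------------------------------------------------------
# survival


def _clean_survival(times, events, groups):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise ValidationError("times, events and groups must align")
    if np.any(times < 0) or not np.isfinite(times).all():
        raise ValidationError("survival times must be finite and non-negative")
    return times, events, groups


def kaplan_meier(times, events, group_assignment) -> dict[object, pd.DataFrame]:
    """Product-limit survival estimate per group (all samples, gray included).

    Returns, per group label, a step-function table with columns ``time``,
    ``survival`` and ``at_risk``. Event-free samples are censored at their
    last follow-up.
    """
    from lifelines import KaplanMeierFitter

    times, events, groups = _clean_survival(times, events, group_assignment)
    out: dict[object, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise DegenerateGroupError(f"empty survival group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        out[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": at_risk.to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    if not out:
        raise DegenerateGroupError("no survival groups")
    return out


def logrank_test(times, events, group_assignment) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lifelines_logrank

    times, events, groups = _clean_survival(times, events, group_assignment)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise DegenerateGroupError("log-rank test requires exactly two groups")
    a = groups == labels[0]
    b = groups == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise DegenerateGroupError("empty survival group")
    res = _lifelines_logrank(times[a], times[b], events[a], events[b])
    return float(res.test_statistic), float(res.p_value)
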