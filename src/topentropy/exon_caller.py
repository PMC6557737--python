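"""Threshold classification of position scores and per-nucleotide evaluation.

Exons sit in low-entropy stretches of the SVD score curve (coding
sequence is more repetitive/conserved than intronic background), so the
default call direction labels a base "exon" when its score is at or
below the cutoff.  Evaluation is per-nucleotide: confusion counts,
accuracy, and a threshold-sweep ROC with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy_signal import PositionScore
from .sequence_io import AnnotationSet, GenomicInterval

__all__ = [
    "LOW_IS_EXON",
    "HIGH_IS_EXON",
    "CallResult",
    "ConfusionCounts",
    "ROCResult",
    "call_regions",
    "confusion",
    "roc_auc",
    "auc_from_arrays",
]

LOW_IS_EXON = "low_is_exon"
HIGH_IS_EXON = "high_is_exon"
_DIRECTIONS = (LOW_IS_EXON, HIGH_IS_EXON)


@dataclass(frozen=True)
class CallResult:
    """Per-base exon/intron labels plus the merged exon intervals."""

    sequence_id: str
    exon_mask: np.ndarray  # True = exon
    called_intervals: tuple[GenomicInterval, ...]
    threshold: float
    direction: str


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-nucleotide confusion counts (exon = positive class)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


@dataclass(frozen=True)
class ROCResult:
    """Threshold sweep: one (fpr, tpr) point per unique score value."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _runs_to_intervals(mask: np.ndarray, sequence_id: str) -> tuple[GenomicInterval, ...]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return tuple(
        GenomicInterval(sequence_id, int(s), int(e), "exon")
        for s, e in zip(starts, ends)
    )


def call_regions(
    score: PositionScore, threshold: float = 0.012, direction: str = LOW_IS_EXON
) -> CallResult:
    """Label each base exon/intron by thresholding its score.

    Ties at the threshold are labeled exon (the comparison is inclusive)
    so the boundary is deterministic.  Maximal runs of exon labels are
    merged into intervals.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; expected one of {_DIRECTIONS}")
    if direction == LOW_IS_EXON:
        mask = score.scores <= threshold
    else:
        mask = score.scores >= threshold
    return CallResult(
        score.sequence_id, mask, _runs_to_intervals(mask, score.sequence_id),
        threshold, direction,
    )


def confusion(
    calls: CallResult, truth: AnnotationSet, region: GenomicInterval
) -> ConfusionCounts:
    """Per-nucleotide confusion counts within ``region``.

    Bases not covered by an exon truth interval count as intron truth.
    """
    if region.end > len(calls.exon_mask) or region.start < 0:
        raise ValueError(
            f"region [{region.start}, {region.end}) outside scored sequence "
            f"of length {len(calls.exon_mask)}"
        )
    truth_mask = truth.label_mask("exon", region.sequence_id, region)
    call_mask = calls.exon_mask[region.start : region.end]
    tp = int(np.sum(call_mask & truth_mask))
    fp = int(np.sum(call_mask & ~truth_mask))
    fn = int(np.sum(~call_mask & truth_mask))
    tn = int(np.sum(~call_mask & ~truth_mask))
    return ConfusionCounts(tp, fp, tn, fn)


def auc_from_arrays(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC by sweeping every unique score value; AUC by the trapezoid rule.

    ``labels`` is boolean (True = positive); higher scores must indicate
    the positive class (negate beforehand if not).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # collapse ties: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(sorted_scores)) if len(scores) > 1 else np.array([], int)
    cut = np.concatenate((distinct, [len(scores) - 1]))
    tp_cum = np.cumsum(sorted_labels)[cut]
    fp_cum = np.cumsum(~sorted_labels)[cut]
    tpr = np.concatenate(([0.0], tp_cum / n_pos))
    fpr = np.concatenate(([0.0], fp_cum / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.concatenate(([np.inf], sorted_scores[cut]))
    return ROCResult(thresholds, fpr, tpr, auc)


def roc_auc(
    score: PositionScore,
    truth: AnnotationSet,
    region: GenomicInterval,
    direction: str = LOW_IS_EXON,
) -> ROCResult:
    """ROC/AUC of the per-base score against exon truth within ``region``.

    For ``low_is_exon`` the score is negated before the standard
    higher-is-positive sweep.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; expected one of {_DIRECTIONS}")
    values = score.scores[region.start : region.end]
    labels = truth.label_mask("exon", region.sequence_id, region)
    if direction == LOW_IS_EXON:
        values = -values
    return auc_from_arrays(values, labels)
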