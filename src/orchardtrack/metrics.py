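"""Instance-segmentation and growth-prediction accuracy metrics.

Precision = TP/(TP+FP), recall = TP/(TP+FN), IoU = |A∩B|/|A∪B| on pixel
masks; MAPE is reported as a fraction (0.079, not 7.9%). The
filtered-vs-averaged IoU contrasts the detection a tracker assigned to a
fruit with the mean over all detections overlapping that fruit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCounts",
    "iou",
    "match_predictions",
    "precision",
    "recall",
    "mape",
    "correlation_and_r2",
    "filtered_vs_averaged_iou",
]


@dataclass
class MatchCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Pixel-count intersection over union of two same-shaped masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks empty")
    return float(np.logical_and(a, b).sum() / union)


def match_predictions(
    predicted: Sequence[np.ndarray],
    annotated: Sequence[np.ndarray],
    iou_threshold: float = 0.5,
) -> tuple[MatchCounts, list[float]]:
    """One-to-one greedy matching by descending IoU.

    Pairs at or above the threshold count as TP; unmatched predictions
    are FP, unmatched annotations FN. Returns the counts and the IoU of
    each TP pair.
    """
    overlaps = []
    for pi, p in enumerate(predicted):
        for ai, a in enumerate(annotated):
            if np.logical_and(p, a).any():
                overlaps.append((iou(p, a), pi, ai))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_p: set[int] = set()
    used_a: set[int] = set()
    tp_ious: list[float] = []
    for value, pi, ai in overlaps:
        if value < iou_threshold or pi in used_p or ai in used_a:
            continue
        used_p.add(pi)
        used_a.add(ai)
        tp_ious.append(value)
    counts = MatchCounts(
        TP=len(tp_ious),
        FP=len(predicted) - len(tp_ious),
        FN=len(annotated) - len(tp_ious),
    )
    return counts, tp_ious


def precision(counts: MatchCounts) -> float | None:
    """TP/(TP+FP); None when undefined (no predictions)."""
    denom = counts.TP + counts.FP
    if denom == 0:
        logger.warning("precision undefined: no predictions")
        return None
    return counts.TP / denom


def recall(counts: MatchCounts) -> float | None:
    """TP/(TP+FN); None when undefined (no annotations)."""
    denom = counts.TP + counts.FN
    if denom == 0:
        logger.warning("recall undefined: no annotations")
        return None
    return counts.TP / denom


def mape(truth: Sequence[float], estimate: Sequence[float]) -> float:
    """Mean absolute percentage error, as a fraction."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape or t.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    if np.any(t == 0):
        raise ValueError("MAPE undefined for zero truth values")
    return float(np.mean(np.abs(e - t) / np.abs(t)))


def correlation_and_r2(
    truth: Sequence[float], estimate: Sequence[float]
) -> tuple[float | None, float | None]:
    """Pearson r and the R^2 of the OLS regression estimate ~ truth."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.size != e.size or t.size < 3:
        raise ValueError("need series of equal length >= 3")
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        logger.warning("correlation undefined for constant series")
        return None, None
    reg = stats.linregress(t, e)
    return float(reg.rvalue), float(reg.rvalue**2)


def filtered_vs_averaged_iou(
    truth_by_day: Mapping[object, np.ndarray],
    detections_by_day: Mapping[object, Sequence[np.ndarray]],
    assigned_by_day: Mapping[object, np.ndarray | None],
) -> dict[object, tuple[float | None, float | None]]:
    """Per-day (filtered IoU, averaged IoU) for one fruit.

    filtered: IoU of the tracker-assigned detection mask against the
    fruit's ground truth; averaged: mean IoU over *all* detections whose
    mask overlaps the ground truth that day. Days without any overlapping
    detection yield (None, None).
    """
    out: dict[object, tuple[float | None, float | None]] = {}
    for day, truth in truth_by_day.items():
        dets = detections_by_day.get(day, [])
        overlapping = [d for d in dets if np.logical_and(d, truth).any()]
        if not overlapping:
            logger.info("day %s: no detection overlaps the ground truth", day)
            out[day] = (None, None)
            continue
        averaged = float(np.mean([iou(d, truth) for d in overlapping]))
        assigned = assigned_by_day.get(day)
        filtered = None
        if assigned is not None and np.logical_and(assigned, truth).any():
            filtered = iou(assigned, truth)
        out[day] = (filtered, averaged)
    return out


def identity_accuracy(
    assignments: Sequence[tuple[int, int | None]],
) -> float:
    """Fraction of (true id, assigned track) pairs consistent with a
    majority-vote mapping from track to true id.

    ``assignments`` holds one entry per ground-truth observation:
    (true instance id, track id the tracker credited, or None if missed).
    """
    if not assignments:
        return math.nan
    votes: dict[int, dict[int, int]] = {}
    for true_id, track_id in assignments:
        if track_id is None:
            continue
        votes.setdefault(track_id, {}).setdefault(true_id, 0)
        votes[track_id][true_id] += 1
    track_to_true = {
        tid: max(counts, key=counts.get) for tid, counts in votes.items()
    }
    correct = sum(
        1
        for true_id, track_id in assignments
        if track_id is not None and track_to_true.get(track_id) == true_id
    )
    return correct / len(assignments)
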