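"""Detection scoring: DA/FA, ROC sweep over the final threshold, precision/F1.

Detection accuracy DA = true detections / total ground-truth targets;
false-alarm rate FA = false detections / frame count. The ROC traces DA
against FA as the final detection threshold sweeps, and ``da_at_fa``
interpolates DA at a requested false-alarm level (the headline operating
point is FA = 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .feedback import Detection
from .suppression import final_detections

__all__ = [
    "MatchResult",
    "RocCurve",
    "match_detections",
    "detection_metrics",
    "roc_curve",
    "da_at_fa",
    "precision_f1",
]


@dataclass
class MatchResult:
    """Per-frame and total matching counts of detections vs ground truth."""

    true_detections: int = 0
    total_targets: int = 0
    false_detections: int = 0
    image_count: int = 0
    per_frame: list[tuple[int, int, int]] = field(default_factory=list)  # (frame, tp, fp)


@dataclass(frozen=True)
class RocCurve:
    """Operating points (threshold, FA, DA), ordered by FA ascending."""

    points: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("ROC curve needs at least one point")


def match_detections(
    detections_by_frame: dict[int, list[Detection]],
    gt_by_frame: dict[int, list[tuple[float, float]]],
    epsilon: float = 5.0,
) -> MatchResult:
    """Score detections against ground truth, strict per-frame matching.

    A target counts as detected if at least one detection lies within
    ``epsilon`` px of it; assignment is nearest-first and one-to-one, so a
    second detection near an already-claimed target is a false detection.
    Frames considered are the union of frames present in either mapping.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    result = MatchResult()
    frames = sorted(set(detections_by_frame) | set(gt_by_frame))
    for t in frames:
        dets = detections_by_frame.get(t, [])
        targets = gt_by_frame.get(t, [])
        pairs = []
        for di, det in enumerate(dets):
            for gi, (gr, gc) in enumerate(targets):
                dist = math.hypot(det.position[0] - gr, det.position[1] - gc)
                if dist <= epsilon:
                    pairs.append((dist, di, gi))
        pairs.sort()
        used_d: set[int] = set()
        used_g: set[int] = set()
        for dist, di, gi in pairs:
            if di in used_d or gi in used_g:
                continue
            used_d.add(di)
            used_g.add(gi)
        tp = len(used_g)
        fp = len(dets) - len(used_d)
        result.true_detections += tp
        result.false_detections += fp
        result.total_targets += len(targets)
        result.image_count += 1
        result.per_frame.append((t, tp, fp))
    return result


def detection_metrics(m: MatchResult) -> tuple[float, float]:
    """(DA, FA) = (true detections / total targets, false detections / frames)."""
    if m.total_targets <= 0 or m.image_count <= 0:
        raise ValueError("need total_targets > 0 and image_count > 0")
    return m.true_detections / m.total_targets, m.false_detections / m.image_count


def roc_curve(
    suppressed_by_frame: dict[int, np.ndarray],
    gt_by_frame: dict[int, list[tuple[float, float]]],
    thresholds: list[float],
    epsilon: float = 5.0,
    nms_radius: float = 5.0,
) -> RocCurve:
    """Sweep the final detection threshold and score each operating point.

    ``suppressed_by_frame`` holds the per-frame suppressed maps (warm-up
    frames excluded by the caller); detections are re-extracted at each
    threshold with the standard peak/NMS rule.
    """
    if not thresholds:
        raise ValueError("threshold sweep must be non-empty")
    points = []
    for th in thresholds:
        dets = {
            t: final_detections(grid, th, nms_radius, frame=t)
            for t, grid in suppressed_by_frame.items()
        }
        m = match_detections(dets, gt_by_frame, epsilon)
        da, fa = detection_metrics(m)
        points.append((float(th), fa, da))
    points.sort(key=lambda p: (p[1], p[2]))
    return RocCurve(tuple(points))


def da_at_fa(curve: RocCurve, fa: float) -> float:
    """DA linearly interpolated at the requested FA, clamped to curve range."""
    pts = sorted(curve.points, key=lambda p: p[1])
    fas = [p[1] for p in pts]
    das = [p[2] for p in pts]
    if fa <= fas[0]:
        return das[0]
    if fa >= fas[-1]:
        return das[-1]
    return float(np.interp(fa, fas, das))


def precision_f1(m: MatchResult) -> tuple[float, float]:
    """(precision, F1) with recall = DA; both 0 when no detections were made."""
    denom = m.true_detections + m.false_detections
    if denom <= 0:
        return 0.0, 0.0
    precision = m.true_detections / denom
    recall = m.true_detections / m.total_targets if m.total_targets else 0.0
    if precision + recall == 0:
        return precision, 0.0
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, f1
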