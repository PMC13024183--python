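"""Trajectory-based feedback attention: track candidate features across
frames, compute each trajectory's temporal response range, classify true
moving targets, and emit a Gaussian feedback gain map for the next frame.

The discriminative statistic is the *response range* RV — the max minus min of
a trajectory's detector-response trace over a sliding window. A genuinely
moving small target sweeps across changing local background, so its detector
response fluctuates strongly (large RV); a background-locked fake feature
rides along with the translating background and keeps a nearly constant
response (small RV). Trajectories whose RV exceeds the range threshold are
classified as true targets, and an additive Gaussian gain bump is injected at
their positions into both ON and OFF channels on the following frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detection",
    "Trajectory",
    "FeedbackConfig",
    "TrajectoryStore",
    "find_candidates",
    "update_trajectories",
    "response_range",
    "classify_targets",
    "feedback_map",
]


@dataclass(frozen=True)
class Detection:
    """A candidate feature: position (row, col), its D response, and frame."""

    position: tuple[int, int]
    response: float
    frame: int


@dataclass
class Trajectory:
    """One tracked feature: positions, response trace and bookkeeping.

    ``status`` is "active" while matched, "pending" while unmatched within the
    grace period, "terminated" once the miss count exceeds the grace period.
    """

    id: int
    points: list[tuple[int, int, int]] = field(default_factory=list)  # (frame,row,col)
    trace: list[float] = field(default_factory=list)
    t_begin: int = 0
    missed: int = 0
    status: str = "active"

    @property
    def last_position(self) -> tuple[int, int]:
        return self.points[-1][1], self.points[-1][2]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    def append(self, frame: int, row: int, col: int, response: float) -> None:
        self.points.append((frame, row, col))
        self.trace.append(response)
        self.missed = 0
        self.status = "active"


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback-loop parameters.

    - ``candidate_threshold`` (ϑ, response units): D peaks below it are ignored.
    - ``range_threshold`` (υ): RV above it marks a trajectory as a true target.
    - ``gain`` (a): amplitude coefficient of the Gaussian feedback bump.
    - ``sigma_f`` (px): spatial spread of the bump; ±2σ covers a 5x5 target.
    - ``assoc_radius`` (px): max center distance to join a trajectory between
      consecutive frames.
    - ``grace`` (frames): unmatched frames tolerated (occlusion) before a
      trajectory terminates.
    - ``window`` (frames): sliding-window length for RV.
    - ``nms_radius`` (px): non-maximum-suppression radius for candidate peaks.
    """

    candidate_threshold: float = 5.0
    range_threshold: float = 35.0
    gain: float = 30.0
    sigma_f: float = 2.0
    assoc_radius: float = 5.0
    grace: int = 3
    window: int = 75
    nms_radius: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "candidate_threshold", "range_threshold", "gain", "sigma_f",
            "assoc_radius", "grace", "window", "nms_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class TrajectoryStore:
    """Mutable collection of trajectories with deterministic id allocation."""

    def __init__(self) -> None:
        self.trajectories: list[Trajectory] = []
        self._next_id = 0

    def new(self, frame: int, row: int, col: int, response: float) -> Trajectory:
        traj = Trajectory(id=self._next_id, t_begin=frame)
        self._next_id += 1
        traj.append(frame, row, col, response)
        self.trajectories.append(traj)
        return traj

    @property
    def live(self) -> list[Trajectory]:
        """Active and pending (not yet terminated) trajectories, by id."""
        return [t for t in self.trajectories if t.status != "terminated"]


def find_candidates(d_grid: np.ndarray, cfg: FeedbackConfig, frame: int) -> list[Detection]:
    """Peaks of the inhibited STMD map D strictly above the candidate threshold.

    Greedy non-maximum suppression: suprathreshold pixels are visited in order
    of decreasing response (ties broken row-major) and kept only if no
    already-kept peak lies within ``nms_radius`` (Euclidean).
    """
    rows, cols = np.nonzero(d_grid > cfg.candidate_threshold)
    if rows.size == 0:
        return []
    resp = d_grid[rows, cols]
    # sort by (-response, row, col): stable lexsort, last key primary
    order = np.lexsort((cols, rows, -resp))
    kept_r: list[int] = []
    kept_c: list[int] = []
    kept: list[Detection] = []
    r2 = cfg.nms_radius**2
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        ok = True
        for kr, kc in zip(kept_r, kept_c):
            if (r - kr) ** 2 + (c - kc) ** 2 <= r2:
                ok = False
                break
        if ok:
            kept_r.append(r)
            kept_c.append(c)
            kept.append(Detection((r, c), float(resp[i]), frame))
    return kept


def update_trajectories(
    store: TrajectoryStore,
    detections: list[Detection],
    t: int,
    cfg: FeedbackConfig,
) -> TrajectoryStore:
    """Associate frame-t detections with live trajectories (greedy nearest pair).

    All (trajectory, detection) pairs within ``assoc_radius`` are ranked by
    (distance, trajectory id, detection index) and assigned greedily, each side
    matched at most once. Unmatched detections seed new trajectories; unmatched
    trajectories increment their miss count, become pending, and terminate when
    the count exceeds the grace period. A pending trajectory that re-matches
    resumes as active with the miss count reset.
    """
    for det in detections:
        if det.frame != t:
            raise ValueError(f"detection from frame {det.frame} given at frame {t}")
    live = store.live
    pairs: list[tuple[float, int, int]] = []
    for ti, traj in enumerate(live):
        lr, lc = traj.last_position
        for di, det in enumerate(detections):
            dist = math.hypot(det.position[0] - lr, det.position[1] - lc)
            if dist <= cfg.assoc_radius:
                pairs.append((dist, ti, di))
    pairs.sort()
    matched_t: set[int] = set()
    matched_d: set[int] = set()
    for dist, ti, di in pairs:
        if ti in matched_t or di in matched_d:
            continue
        matched_t.add(ti)
        matched_d.add(di)
        det = detections[di]
        live[ti].append(t, det.position[0], det.position[1], det.response)
    for ti, traj in enumerate(live):
        if ti not in matched_t:
            traj.missed += 1
            traj.status = "terminated" if traj.missed > cfg.grace else "pending"
    for di, det in enumerate(detections):
        if di not in matched_d:
            store.new(t, det.position[0], det.position[1], det.response)
    return store


def response_range(traj: Trajectory, window: int | float = 75) -> float:
    """Max minus min of the last ``min(window, len)`` trace values (RV >= 0)."""
    if not traj.trace:
        raise ValueError("trajectory has an empty response trace")
    if math.isinf(window):
        tail = traj.trace
    else:
        tail = traj.trace[-int(window):]
    return max(tail) - min(tail)


def classify_targets(
    store: TrajectoryStore, cfg: FeedbackConfig, t: int
) -> list[tuple[int, int]]:
    """Current positions of active trajectories whose RV exceeds the threshold."""
    out: list[tuple[int, int]] = []
    for traj in store.trajectories:
        if traj.status != "active":
            continue
        if response_range(traj, cfg.window) > cfg.range_threshold:
            out.append(traj.last_position)
    return out


def feedback_map(
    positions: list[tuple[int, int]],
    cfg: FeedbackConfig,
    shape: tuple[int, int],
) -> np.ndarray:
    """Superposed Gaussian gain bumps at classified target positions.

    Each target contributes ``a / (2 pi sigma_f^2) * exp(-d^2 / (2 sigma_f^2))``;
    with defaults (a=30, sigma_f=2) the per-target peak is 30/(8π) ≈ 1.194.
    Returns the all-zero map when no targets are classified.
    """
    gain = np.zeros(shape, dtype=np.float64)
    if not positions:
        return gain
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=np.float64),
        np.arange(shape[1], dtype=np.float64),
        indexing="ij",
    )
    amp = cfg.gain / (2.0 * math.pi * cfg.sigma_f**2)
    for r, c in positions:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"target position ({r}, {c}) outside grid {shape}")
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        gain += amp * np.exp(-d2 / (2.0 * cfg.sigma_f**2))
    return gain
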