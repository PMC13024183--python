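"""Closed-loop per-frame orchestration.

Each frame flows detect → track → classify → feed back → suppress:

1. The feedforward pathway (ommatidia → LMC → ON/OFF → delay) processes the
   new frame; the feedback map built from frame t-1 is injected into both
   channels (one-frame latency; zero at t=0), then correlation and lateral
   inhibition yield the modulated detector map D'.
2. Candidate peaks of D' update the trajectory store; trajectories whose
   response range exceeds the range threshold are classified as true targets
   and define the feedback map for frame t+1.
3. A large-scale blurred copy of D' is subtracted (global suppression) and
   the result thresholded into final detections for frame t.

Ablation modes: ``no_feedback`` forces F ≡ 0; ``no_suppression`` emits D'
directly as the suppressed map; ``estmd_baseline`` combines both, reducing
the system to the classical feedforward small-target detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .feedback import (
    Detection,
    FeedbackConfig,
    TrajectoryStore,
    classify_targets,
    feedback_map,
    find_candidates,
    update_trajectories,
)
from .pathway import MotionPathway, PathwayConfig
from .suppression import SuppressionConfig, estimate_background, final_detections, suppress

__all__ = ["PipelineConfig", "FrameResult", "Pipeline", "run_sequence", "MODES"]

logger = logging.getLogger(__name__)

MODES = ("full", "no_feedback", "no_suppression", "estmd_baseline")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration: pathway + feedback loop + suppression + mode."""

    pathway: PathwayConfig = field(default_factory=PathwayConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    suppression: SuppressionConfig = field(default_factory=SuppressionConfig)
    mode: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def feedback_enabled(self) -> bool:
        return self.mode in ("full", "no_suppression")

    @property
    def suppression_enabled(self) -> bool:
        return self.mode in ("full", "no_feedback")


@dataclass
class FrameResult:
    """Outputs for one frame; diagnostic grids retained only on request."""

    frame: int
    detections: list[Detection]
    warmup: bool
    diagnostics: dict[str, np.ndarray] | None = None


class Pipeline:
    """Stateful closed-loop detector; feed frames via :meth:`step`."""

    def __init__(self, cfg: PipelineConfig | None = None) -> None:
        self.cfg = cfg or PipelineConfig()
        self.pathway = MotionPathway(self.cfg.pathway)
        self.store = TrajectoryStore()
        self._shape: tuple[int, int] | None = None
        self._t = 0

    @property
    def warmup_frames(self) -> int:
        return self.pathway.warmup_frames

    def step(self, frame: np.ndarray, keep_diagnostics: bool = False) -> FrameResult:
        cfg = self.cfg
        t = self._t
        frame = np.asarray(frame, dtype=np.float64)
        if self._shape is None:
            self._shape = frame.shape
        elif frame.shape != self._shape:
            raise ValueError(
                f"frame shape changed mid-sequence: {frame.shape} != {self._shape}"
            )

        if not cfg.feedback_enabled:
            self.pathway.state.feedback = None  # forces F = 0
        grids = self.pathway.step(frame)
        d_prime = grids["D"]
        warmup = t < self.warmup_frames

        # trajectory update + classification builds the feedback for t+1
        if not warmup:
            cands = find_candidates(d_prime, cfg.feedback, t)
            update_trajectories(self.store, cands, t, cfg.feedback)
            if cfg.feedback_enabled:
                positions = classify_targets(self.store, cfg.feedback, t)
                self.pathway.state.feedback = feedback_map(
                    positions, cfg.feedback, frame.shape
                )

        if cfg.suppression_enabled:
            b = estimate_background(d_prime, cfg.suppression)
            suppressed = suppress(d_prime, b, cfg.suppression.strength)
        else:
            suppressed = d_prime
        if warmup:
            dets: list[Detection] = []
        else:
            dets = final_detections(
                suppressed,
                cfg.suppression.final_threshold,
                cfg.feedback.nms_radius,
                frame=t,
            )
        logger.info("frame %d: %d detections%s", t, len(dets), " (warmup)" if warmup else "")

        diagnostics = None
        if keep_diagnostics:
            diagnostics = dict(grids)
            diagnostics["suppressed"] = suppressed
        self._t += 1
        return FrameResult(frame=t, detections=dets, warmup=warmup, diagnostics=diagnostics)


def run_sequence(
    frames: np.ndarray,
    cfg: PipelineConfig | None = None,
    keep_diagnostics: bool = False,
) -> list[FrameResult]:
    """Fold the closed loop over an ordered frame stack (n, h, w)."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, height, width) stack")
    pipe = Pipeline(cfg)
    return [pipe.step(f, keep_diagnostics=keep_diagnostics) for f in frames]
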