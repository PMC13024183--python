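"""Feedforward STMD motion-detection pathway.

Stages, per frame, for a grayscale luminance grid I(row, col) on the 0-255
scale:

1. Ommatidia: spatial Gaussian blur ``P = I * G_sigma1`` (photoreceptor optics).
2. LMC: causal temporal band-pass ``L(t) = sum_s P(t-s) H[s]`` with the
   zero-sum difference-of-Gamma kernel H, removing static (DC) luminance.
3. ON/OFF split (Tm3/Tm1): half-wave rectification of L into a luminance-
   increment channel ``S_ON = [L]_+`` and a decrement channel carrying the
   rectified magnitude ``-[L]_-``; the OFF channel is then temporally delayed
   by a Gamma kernel so that, for a dark target whose leading edge darkens a
   pixel and whose trailing edge later brightens it, the delayed OFF signal
   coincides with the ON signal.
4. Feedback injection: an externally supplied nonnegative gain field F (from
   the previous frame's trajectory classification) is added to both channels.
5. STMD correlation: elementwise product of the two channels.
6. Lateral inhibition: convolution with a center-positive / surround-negative
   kernel followed by half-wave rectification, suppressing extended stimuli.

All 2-D convolutions use replicate-edge padding; temporal convolutions pad
missing history with zeros (warm-up). Coordinates are (row, col), 0-based.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .kernels import (
    GammaSpec,
    SpatialKernel,
    TemporalKernel,
    gamma_kernel,
    gaussian_kernel2d,
    inhibition_kernel,
    temporal_bandpass,
)

__all__ = [
    "PathwayConfig",
    "PathwayState",
    "ommatidia_response",
    "lmc_response",
    "on_off_split",
    "delay_off",
    "inject_feedback",
    "stmd_correlate",
    "lateral_inhibit",
    "MotionPathway",
]


def _conv2d(image: np.ndarray, kernel: SpatialKernel) -> np.ndarray:
    """2-D convolution with replicate-edge padding.

    ``scipy.ndimage.correlate`` with the flipped kernel implements true
    convolution; all kernels used here are centrosymmetric so the flip is a
    formality, but it keeps the operation equal to the textbook definition.
    """
    w = kernel.weights[::-1, ::-1]
    return correlate(image, w, mode="nearest")


@dataclass(frozen=True)
class PathwayConfig:
    """Coefficients of the feedforward pathway.

    Defaults follow the reference tuning for a preferred 5x5 px dark target
    at ~0.25 px/frame: the OFF delay ``tau3 = 25`` frames approximates the
    time the target takes to traverse one pixel footprint.
    """

    sigma1: float = 1.0
    gaussian_size: int = 3
    n1: int = 2
    tau1: float = 3.0
    n2: int = 6
    tau2: float = 9.0
    bandpass_length: int = 2 * (3 + 9)
    n3: int = 5
    tau3: float = 25.0
    delay_length: int = 3 * 25
    sigma2: float = 1.5
    sigma3: float = 3.0
    e: float = 1.0
    rho: float = 0.0
    phi: float = 1.0
    psi: float = 3.0
    inhibition_size: int = 13

    def build_kernels(
        self,
    ) -> tuple[SpatialKernel, TemporalKernel, TemporalKernel, SpatialKernel]:
        """Instantiate (G_sigma1, H, Gamma_n3_tau3, K)."""
        g1 = gaussian_kernel2d(self.sigma1, self.gaussian_size)
        h = temporal_bandpass(
            self.n1, self.tau1, self.n2, self.tau2, self.bandpass_length
        )
        gam3 = gamma_kernel(GammaSpec(self.n3, self.tau3, self.delay_length))
        k = inhibition_kernel(
            self.sigma2, self.sigma3, self.e, self.rho,
            self.phi, self.psi, self.inhibition_size,
        )
        return g1, h, gam3, k


@dataclass
class PathwayState:
    """Ring buffers of past stage outputs; newest grid first.

    ``p_history[s]`` is the ommatidia output ``s`` frames ago; likewise
    ``off_history`` for the rectified OFF (luminance-decrement) magnitudes.
    The feedback map is initialized to all-zero.
    """

    p_history: deque = field(default_factory=deque)
    off_history: deque = field(default_factory=deque)
    feedback: np.ndarray | None = None
    frames_seen: int = 0

    def push_p(self, grid: np.ndarray, maxlen: int) -> None:
        self.p_history.appendleft(grid)
        while len(self.p_history) > maxlen:
            self.p_history.pop()

    def push_off(self, grid: np.ndarray, maxlen: int) -> None:
        self.off_history.appendleft(grid)
        while len(self.off_history) > maxlen:
            self.off_history.pop()


def ommatidia_response(frame: np.ndarray, g1: SpatialKernel) -> np.ndarray:
    """Spatial Gaussian blur of the luminance grid (photoreceptor optics)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D luminance grid")
    if frame.shape[0] < g1.shape[0] or frame.shape[1] < g1.shape[1]:
        raise ValueError(
            f"frame {frame.shape} smaller than kernel {g1.shape}"
        )
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    return _conv2d(frame, g1)


def _temporal_apply(history: deque, weights: np.ndarray) -> np.ndarray:
    """Causal temporal convolution: sum_s history[s] * weights[s].

    Missing history (warm-up) is treated as zero.
    """
    out = np.zeros_like(history[0])
    for s, grid in enumerate(history):
        if s >= weights.size:
            break
        out += grid * weights[s]
    return out


def lmc_response(state: PathwayState, h: TemporalKernel) -> np.ndarray:
    """Temporal band-pass of the ommatidia history (lamina LMC stage)."""
    if not state.p_history:
        raise ValueError("no ommatidia history available")
    return _temporal_apply(state.p_history, h.weights)


def on_off_split(l_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectify L into ON and OFF channels.

    The OFF channel carries the rectified magnitude ``-min(L, 0)`` so both
    outputs are nonnegative and ``S_ON - OFF_raw`` reconstructs L.
    """
    return np.maximum(l_grid, 0.0), -np.minimum(l_grid, 0.0)


def delay_off(state: PathwayState, gam3: TemporalKernel) -> np.ndarray:
    """Gamma-delay the rectified OFF history (Tm1 temporal lag)."""
    if not state.off_history:
        raise ValueError("no OFF history available")
    return _temporal_apply(state.off_history, gam3.weights)


def inject_feedback(
    s_on: np.ndarray, s_off: np.ndarray, feedback: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Add the feedback gain field to both channels elementwise."""
    if s_on.shape != s_off.shape or s_on.shape != feedback.shape:
        raise ValueError(
            f"shape mismatch: ON {s_on.shape}, OFF {s_off.shape}, "
            f"feedback {feedback.shape}"
        )
    return s_on + feedback, s_off + feedback


def stmd_correlate(s_on: np.ndarray, s_off: np.ndarray) -> np.ndarray:
    """Nonlinear multiplicative integration of ON and delayed OFF channels."""
    return s_on * s_off


def lateral_inhibit(s_grid: np.ndarray, k: SpatialKernel) -> np.ndarray:
    """Center-surround inhibition followed by half-wave rectification."""
    return np.maximum(_conv2d(s_grid, k), 0.0)


class MotionPathway:
    """Stateful per-frame driver of the feedforward pathway.

    Call :meth:`step` with successive frames; it returns the per-stage grids.
    The feedback field for stage 4 comes from ``state.feedback`` (set by the
    caller, e.g. the closed-loop pipeline) and defaults to zero.
    """

    def __init__(self, cfg: PathwayConfig | None = None) -> None:
        self.cfg = cfg or PathwayConfig()
        self.g1, self.h, self.gam3, self.k = self.cfg.build_kernels()
        self.state = PathwayState()

    @property
    def warmup_frames(self) -> int:
        """Frames to discard before outputs are trustworthy."""
        return self.cfg.bandpass_length

    def step(self, frame: np.ndarray) -> dict[str, np.ndarray]:
        """Process one frame; returns all intermediate grids keyed by stage."""
        st = self.state
        p = ommatidia_response(frame, self.g1)
        st.push_p(p, self.cfg.bandpass_length)
        l_grid = lmc_response(st, self.h)
        s_on, off_raw = on_off_split(l_grid)
        st.push_off(off_raw, self.cfg.delay_length)
        s_off = delay_off(st, self.gam3)
        if st.feedback is None:
            feedback = np.zeros_like(p)
        else:
            feedback = st.feedback
        s_on_p, s_off_p = inject_feedback(s_on, s_off, feedback)
        s = stmd_correlate(s_on_p, s_off_p)
        d = lateral_inhibit(s, self.k)
        st.frames_seen += 1
        return {
            "P": p, "L": l_grid, "SON": s_on, "SOFF": s_off,
            "F": feedback, "S": s, "D": d,
        }
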