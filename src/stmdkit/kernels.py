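"""Spatial and temporal filter kernels for the STMD visual pathway.

Temporal kernels are sampled at integer frame lags (lag 0 = current frame);
the Gamma-kernel time constant ``tau`` is therefore expressed in frames.
Spatial kernels are 2-D grids with odd side lengths centered on the middle
sample; coordinates follow the (row, col) convention with row increasing
downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GammaSpec",
    "TemporalKernel",
    "SpatialKernel",
    "gamma_kernel",
    "temporal_bandpass",
    "gaussian_kernel2d",
    "inhibition_kernel",
]


class KernelSpecError(ValueError):
    """Raised when a kernel specification is invalid."""


@dataclass(frozen=True)
class GammaSpec:
    """Specification of a discrete Gamma kernel.

    Parameters
    ----------
    order_n : int
        Kernel order ``n`` (>= 1); controls the sharpness of the hump.
    tau : float
        Temporal constant in frames (> 0); the kernel peaks at lag ``tau``.
    length : int
        Number of integer lags sampled (>= 1).
    """

    order_n: int
    tau: float
    length: int

    def __post_init__(self) -> None:
        if self.order_n < 1:
            raise KernelSpecError(f"Gamma order must be >= 1, got {self.order_n}")
        if self.tau <= 0:
            raise KernelSpecError(f"Gamma tau must be > 0, got {self.tau}")
        if self.length < 1:
            raise KernelSpecError(f"Gamma length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class TemporalKernel:
    """Causal temporal kernel: ``weights[s]`` applies to the frame ``s`` lags ago."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size < 1:
            raise KernelSpecError("temporal kernel weights must be a 1-D sequence")
        if not np.all(np.isfinite(w)):
            raise KernelSpecError("temporal kernel weights must be finite")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class SpatialKernel:
    """2-D kernel with odd side lengths; ``center`` is the geometric middle."""

    weights: np.ndarray
    center: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise KernelSpecError("spatial kernel weights must be 2-D")
        if w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise KernelSpecError(f"spatial kernel sides must be odd, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise KernelSpecError("spatial kernel weights must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "center", (w.shape[0] // 2, w.shape[1] // 2))

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def gamma_kernel(spec: GammaSpec) -> TemporalKernel:
    """Sample a Gamma kernel at integer lags 0..length-1.

    The continuous form is ``(n t)^n e^{-n t / tau} / ((n-1)! tau^{n+1})`` for
    t >= 0 and zero otherwise; it integrates to one and peaks at t = tau.
    The discrete sum approaches 1 as ``length`` grows.
    """
    n, tau, length = spec.order_n, spec.tau, spec.length
    t = np.arange(length, dtype=np.float64)
    # log-domain evaluation keeps large orders stable
    with np.errstate(divide="ignore"):
        logw = n * np.log(n * t, where=t > 0, out=np.full(length, -np.inf)) \
            - n * t / tau - math.lgamma(n) - (n + 1) * math.log(tau)
    w = np.exp(logw)
    w[0] = 0.0  # t^n = 0 at t=0 for n >= 1
    return TemporalKernel(w)


def temporal_bandpass(
    n1: int, tau1: float, n2: int, tau2: float, length: int
) -> TemporalKernel:
    """Band-pass kernel as the difference of a fast and a slow Gamma kernel.

    The raw difference is mean-subtracted so the discrete weight sum is exactly
    zero: convolving any constant (static) sequence yields exactly zero, which
    is the DC-blocking behaviour the lamina stage requires.
    """
    fast = gamma_kernel(GammaSpec(n1, tau1, length)).weights
    slow = gamma_kernel(GammaSpec(n2, tau2, length)).weights
    w = fast - slow
    w = w - w.mean()
    # Kill the floating-point residual so the weight sum is exactly zero.
    # A single correction at one element can leave a sub-ulp residual, so
    # search for an element where absorbing the residual actually moves the
    # computed sum, and repeat until it reaches exactly 0.0.
    for _ in range(100):
        residual = np.sum(w)
        if residual == 0.0:
            break
        for j in np.argsort(np.abs(w))[::-1]:
            trial = w.copy()
            trial[j] -= residual
            if abs(np.sum(trial)) < abs(residual):
                w = trial
                break
        else:
            break  # residual cannot be reduced further
    return TemporalKernel(w)


def gaussian_kernel2d(sigma: float, size: int) -> SpatialKernel:
    """Isotropic 2-D Gaussian on an odd integer grid, renormalized to unit sum.

    Unit sum makes convolution of a constant image an identity, so smoothing
    preserves mean luminance.
    """
    if sigma <= 0:
        raise KernelSpecError(f"sigma must be > 0, got {sigma}")
    if size < 1 or size % 2 == 0:
        raise KernelSpecError(f"size must be odd and >= 1, got {size}")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    w = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    w /= w.sum()
    return SpatialKernel(w)


def _gaussian_density2d(sigma: float, size: int) -> np.ndarray:
    """Raw continuous-density samples (no renormalization)."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * math.pi * sigma**2)


def inhibition_kernel(
    sigma2: float = 1.5,
    sigma3: float = 3.0,
    e: float = 1.0,
    rho: float = 0.0,
    phi: float = 1.0,
    psi: float = 3.0,
    size: int = 13,
) -> SpatialKernel:
    """Center-surround lateral-inhibition kernel.

    Built from a difference of Gaussian densities ``g = G_{sigma2} - e G_{sigma3}
    - rho`` (raw density samples, not renormalized), split by sign and reweighted:
    ``K = phi [g]_+ + psi [g]_-``. With the defaults the center is positive and
    the surround negative, which suppresses spatially extended activation and
    confers small-target size selectivity.
    """
    import warnings

    if size < 1 or size % 2 == 0:
        raise KernelSpecError(f"size must be odd and >= 1, got {size}")
    if sigma2 <= 0 or sigma3 <= 0:
        raise KernelSpecError("sigma2 and sigma3 must be > 0")
    if sigma2 >= sigma3:
        warnings.warn(
            "sigma2 >= sigma3: kernel lacks center-surround structure",
            stacklevel=2,
        )
    g = _gaussian_density2d(sigma2, size) - e * _gaussian_density2d(sigma3, size) - rho
    k = phi * np.maximum(g, 0.0) + psi * np.minimum(g, 0.0)
    return SpatialKernel(k)
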