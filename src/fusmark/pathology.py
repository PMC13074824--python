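"""Ablated-volume estimation from serial gross-pathology slices.

Each slice contributes area x thickness; the combined standard uncertainty
follows first-order (GUM-style) propagation assuming independent components:

    V     = sum_i A_i * t_i
    u(V)^2 = sum_i [ t_i^2 * u(A_i)^2 + A_i^2 * u(t_i)^2 ]

Thickness uncertainties come from repeat caliper measurements; when no
per-slice area uncertainty is supplied, a boundary-pixel heuristic is used:
annotation uncertainty concentrates at the ablated-region boundary, so
u(A) = (boundary pixel count) * (pixel area) / sqrt(12), the standard
deviation of a +/- half-pixel uniform error per boundary pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import SliceStack

__all__ = ["VolumeEstimate", "slice_area", "boundary_area_sd", "ablated_volume"]


@dataclass
class VolumeEstimate:
    """Ablated volume with combined standard uncertainty, both in cm^3."""

    volume: float
    combined_standard_uncertainty: float

    def __post_init__(self) -> None:
        if self.combined_standard_uncertainty < 0:
            raise ValueError("uncertainty must be nonnegative")


def _check_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        arr = arr.astype(bool)
    return arr


def slice_area(mask: np.ndarray, pixel_scale: float) -> float:
    """Ablated area of one slice in cm^2 (pixel count x pixel_scale^2)."""
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    mask = _check_binary(mask)
    return float(mask.sum()) * pixel_scale**2 * 1e4


def boundary_area_sd(mask: np.ndarray, pixel_scale: float) -> float:
    """Boundary-pixel heuristic for per-slice area uncertainty, in m^2."""
    mask = _check_binary(mask)
    if not mask.any():
        return 0.0
    interior = ndimage.binary_erosion(mask)
    n_boundary = int(mask.sum() - interior.sum())
    return n_boundary * pixel_scale**2 / np.sqrt(12.0)


def ablated_volume(stack: SliceStack) -> VolumeEstimate:
    """Estimate ablated volume and combined standard uncertainty from a stack.

    Slices with zero ablated area contribute nothing to the volume or its
    uncertainty.  Area uncertainties are taken from ``stack.area_sd`` when
    present, otherwise from the boundary-pixel heuristic.  Volume and
    uncertainty are invariant under slice reordering, and all-zero component
    uncertainties yield exactly zero combined uncertainty.
    """
    if len(stack) == 0:
        raise ValueError("stack must contain at least one slice")
    ps = stack.pixel_scale
    areas = np.array([float(_check_binary(m).sum()) * ps**2 for m in stack.masks])
    if stack.area_sd is not None:
        u_area = np.asarray(stack.area_sd, dtype=float)
        if u_area.shape != areas.shape:
            raise ValueError("area_sd must provide one value per slice")
    else:
        u_area = np.array([boundary_area_sd(m, ps) for m in stack.masks])

    nonzero = areas > 0
    if nonzero.any() and not np.isfinite(stack.thickness_mean[nonzero]).all():
        raise ValueError("missing thickness for a nonzero-area slice")

    t = stack.thickness_mean
    u_t = stack.thickness_sd
    volume = float((areas[nonzero] * t[nonzero]).sum())
    var = float(
        (t[nonzero] ** 2 * u_area[nonzero] ** 2).sum()
        + (areas[nonzero] ** 2 * u_t[nonzero] ** 2).sum()
    )
    return VolumeEstimate(
        volume=volume * 1e6,
        combined_standard_uncertainty=float(np.sqrt(var)) * 1e6,
    )
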