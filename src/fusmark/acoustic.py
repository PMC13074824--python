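"""Angular-spectrum field reconstruction and focus metrics.

A single hydrophone-scanned plane of complex pressure determines the whole
monochromatic field: decomposing the plane into plane waves by 2D FFT,
multiplying each component by the transfer function ``H = exp(i*kz*dz)``
with ``kz = sqrt(k^2 - kx^2 - ky^2)``, and inverting the FFT reconstructs
the field at any parallel plane ("spatial planar projection").  Evanescent
components (``kx^2 + ky^2 > k^2``) are zeroed for both propagation
directions: backward projection would otherwise amplify them without bound,
and a hydrophone plane several wavelengths from any source carries no usable
evanescent information anyway.

Field-comparison and focus metrics follow hydrophone-scan practice for
focused-ultrasound beams: normalized magnitude RMSD between volumes, the
focus defined as the largest contiguous region above half the maximum
amplitude, and focus displacement as the shift of the amplitude peak against
a paired control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import PressurePlane, PressureVolume

__all__ = [
    "FocusMetrics",
    "angular_spectrum_propagate",
    "project_plane",
    "rmsd_volumes",
    "largest_contiguous_region",
    "focus_metrics",
    "insertion_loss_from_planes",
]

logger = logging.getLogger(__name__)


def _pad_center(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=a.dtype)
    oy = (shape[0] - a.shape[0]) // 2
    ox = (shape[1] - a.shape[1]) // 2
    out[oy : oy + a.shape[0], ox : ox + a.shape[1]] = a
    return out


def _crop_center(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    oy = (a.shape[0] - shape[0]) // 2
    ox = (a.shape[1] - shape[1]) // 2
    return a[oy : oy + shape[0], ox : ox + shape[1]]


def angular_spectrum_propagate(
    field: np.ndarray,
    spacing: float,
    k: float,
    dz: float,
    pad_factor: int = 2,
) -> np.ndarray:
    """Propagate a complex 2D field by a signed axial distance ``dz``.

    The field is zero-padded to ``pad_factor`` times its extent per axis
    (suppressing circular-convolution wraparound), transformed, multiplied by
    the angular-spectrum transfer function, inverted and cropped back.
    ``dz == 0`` returns the input unchanged (pad round-trip only), so the
    identity contract holds for arbitrary input.

    Evanescent components are removed for dz != 0 in either direction.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    field = np.asarray(field, dtype=complex)
    if dz == 0:
        return field.copy()
    shape = (field.shape[0] * pad_factor, field.shape[1] * pad_factor)
    padded = _pad_center(field, shape) if pad_factor > 1 else field

    ky = 2 * np.pi * np.fft.fftfreq(shape[0], spacing)
    kx = 2 * np.pi * np.fft.fftfreq(shape[1], spacing)
    kz_sq = k**2 - ky[:, None] ** 2 - kx[None, :] ** 2
    propagating = kz_sq > 0
    transfer = np.zeros(shape, dtype=complex)
    transfer[propagating] = np.exp(1j * np.sqrt(kz_sq[propagating]) * dz)

    spectrum = np.fft.fft2(padded)
    out = np.fft.ifft2(spectrum * transfer)
    if pad_factor > 1:
        out = _crop_center(out, field.shape)
    return out


def project_plane(
    plane: PressurePlane,
    z_targets,
    pad_factor: int = 2,
    keep_complex: bool = True,
) -> PressureVolume:
    """Reconstruct a volume from a single plane via angular-spectrum projection.

    Parameters
    ----------
    plane : PressurePlane
        Measured (or simulated) complex plane at ``plane.z_offset``.
    z_targets : sequence of float
        Signed axial target positions relative to the natural focus (m).
        Must be uniformly spaced when more than one target is given so the
        result lives on a regular grid.
    pad_factor : int
        Zero-padding multiple per axis (default 2).
    keep_complex : bool
        Also store the complex field in the returned volume.

    Notes
    -----
    A padded aperture of half-extent L can only angularly cover targets out
    to roughly ``|dz| < L_pad - L_window``; beyond that the reconstruction is
    truncated and a warning is issued (heuristic, not an error).
    """
    z_targets = np.atleast_1d(np.asarray(z_targets, dtype=float))
    if z_targets.size > 1:
        steps = np.diff(z_targets)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("z_targets must be uniformly spaced")
        dz_grid = float(steps[0])
        if dz_grid <= 0:
            raise ValueError("z_targets must be increasing")
    else:
        dz_grid = plane.spacing  # nominal; single-plane volumes rarely need it

    half_window = plane.spacing * max(plane.data.shape) / 2
    reach = half_window * (2 * pad_factor - 2) if pad_factor > 1 else half_window
    max_dz = np.max(np.abs(z_targets - plane.z_offset))
    if max_dz > reach:
        warnings.warn(
            f"target {max_dz * 1e3:.1f} mm from the measured plane exceeds the "
            f"padded-aperture coverage heuristic ({reach * 1e3:.1f} mm); the "
            "reconstruction may be truncated",
            stacklevel=2,
        )

    k = plane.wavenumber
    frames = np.empty((z_targets.size,) + plane.data.shape, dtype=complex)
    for i, zt in enumerate(z_targets):
        frames[i] = angular_spectrum_propagate(
            plane.data, plane.spacing, k, zt - plane.z_offset, pad_factor
        )

    ny, nx = plane.data.shape
    origin = (
        float(z_targets[0]),
        -plane.spacing * (ny - 1) / 2,
        -plane.spacing * (nx - 1) / 2,
    )
    return PressureVolume(
        magnitude=np.abs(frames),
        spacing=(dz_grid, plane.spacing, plane.spacing),
        origin=origin,
        complex_data=frames if keep_complex else None,
    )


def rmsd_volumes(
    test: PressureVolume,
    reference: PressureVolume,
    normalization: str = "peak",
) -> float:
    """Normalized pressure-magnitude root-mean-squared difference.

    ``sqrt(mean((|test| - |reference|)^2))`` divided by a normalizer of the
    reference magnitude: its spatial peak (default), its RMS, or the joint
    peak of both volumes.  Swapping the arguments changes only the
    denominator.
    """
    if not test.same_grid(reference):
        raise ValueError("volumes must share an identical grid")
    diff = test.magnitude - reference.magnitude
    rms = float(np.sqrt(np.mean(diff**2)))
    if normalization == "peak":
        denom = float(reference.magnitude.max())
    elif normalization == "rms":
        denom = float(np.sqrt(np.mean(reference.magnitude**2)))
    elif normalization == "joint_peak":
        denom = float(max(test.magnitude.max(), reference.magnitude.max()))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        raise ValueError("reference volume is identically zero")
    return rms / denom


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in (1, 2, 3):
        raise ValueError("connectivity must be 1 (faces), 2 (+edges) or 3 (+corners)")
    return ndimage.generate_binary_structure(3, connectivity)


def largest_contiguous_region(
    field: np.ndarray,
    threshold: float,
    spacing: tuple[float, float, float],
    connectivity: int = 1,
    strict: bool = True,
) -> tuple[np.ndarray, float]:
    """Largest connected supra-threshold component of a 3D scalar field.

    Returns ``(mask, volume_m3)``; the empty mask with volume 0 is a valid
    result when nothing exceeds the threshold.  ``strict`` selects ``>``
    (amplitude-above-half-maximum rule) vs ``>=`` (dose "at least" rule).
    """
    field = np.asarray(field, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = field > threshold if strict else field >= threshold
    if not above.any():
        return np.zeros_like(above), 0.0
    labels, n = ndimage.label(above, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # ties: lowest label = first in raster order
    mask = labels == best
    volume = float(counts[best - 1]) * float(np.prod(spacing))
    return mask, volume


def _parabolic_refine(field: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    """3-point parabolic sub-voxel peak refinement along each axis."""
    offset = np.zeros(3)
    for ax in range(3):
        i = idx[ax]
        if i == 0 or i == field.shape[ax] - 1:
            continue
        sl = list(idx)
        sl[ax] = slice(i - 1, i + 2)
        a, b, c = field[tuple(sl)]
        denom = a - 2 * b + c
        if denom != 0:
            offset[ax] = 0.5 * (a - c) / denom
    return offset


@dataclass
class FocusMetrics:
    """Paired test-vs-control focus characterization.

    peak_change_vs_control and focus_volume_change are fractional changes
    (0 means identical); displacement_vector is (z, y, x) in metres;
    insertion_loss is in dB (positive = loss).
    """

    peak_pressure: float
    peak_change_vs_control: float
    focus_volume: float
    focus_volume_change: float
    displacement_vector: tuple[float, float, float]
    displacement_total: float
    insertion_loss: float

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.displacement_vector))
        if not np.isclose(norm, self.displacement_total, rtol=1e-9, atol=1e-15):
            raise ValueError("displacement_total must equal |displacement_vector|")


def focus_metrics(
    test: PressureVolume,
    control: PressureVolume,
    connectivity: int = 1,
    refine_subvoxel: bool = False,
) -> FocusMetrics:
    """Characterize a test field against its paired control.

    The focus volume of each field is the largest contiguous region with
    amplitude strictly greater than half that field's own maximum; the
    displacement is the shift of the amplitude argmax (ties broken by first
    occurrence in (z, y, x) raster order; optional 3-point parabolic
    sub-voxel refinement).  Insertion loss is computed on volume peaks as
    ``-20*log10(peak_test/peak_control)``.
    """
    if not test.same_grid(control):
        raise ValueError("test and control must share an identical grid")
    peak_t = float(test.magnitude.max())
    peak_c = float(control.magnitude.max())
    if peak_t == 0:
        raise ValueError("test volume is identically zero")
    if peak_c == 0:
        raise ValueError("control volume is identically zero")

    _, vol_t = largest_contiguous_region(
        test.magnitude, peak_t / 2, test.spacing, connectivity
    )
    _, vol_c = largest_contiguous_region(
        control.magnitude, peak_c / 2, control.spacing, connectivity
    )

    idx_t = np.unravel_index(int(np.argmax(test.magnitude)), test.magnitude.shape)
    idx_c = np.unravel_index(int(np.argmax(control.magnitude)), control.magnitude.shape)
    pos_t = np.asarray(idx_t, dtype=float)
    pos_c = np.asarray(idx_c, dtype=float)
    if refine_subvoxel:
        pos_t += _parabolic_refine(test.magnitude, idx_t)
        pos_c += _parabolic_refine(control.magnitude, idx_c)
    disp = tuple((pos_t - pos_c) * np.asarray(test.spacing))

    return FocusMetrics(
        peak_pressure=peak_t,
        peak_change_vs_control=peak_t / peak_c - 1.0,
        focus_volume=vol_t,
        focus_volume_change=vol_t / vol_c - 1.0 if vol_c > 0 else np.nan,
        displacement_vector=disp,
        displacement_total=float(np.linalg.norm(disp)),
        insertion_loss=-20.0 * np.log10(peak_t / peak_c),
    )


def insertion_loss_from_planes(test: PressurePlane, control: PressurePlane) -> float:
    """In-plane insertion loss variant: dB loss between single-plane peaks."""
    peak_t = float(np.abs(test.data).max())
    peak_c = float(np.abs(control.data).max())
    if peak_t == 0 or peak_c == 0:
        raise ValueError("plane peak is zero")
    return -20.0 * np.log10(peak_t / peak_c)
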