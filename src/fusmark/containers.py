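"""Shared data containers for the acoustic, thermometry and pathology stages.

Axis convention
---------------
All volumetric arrays are indexed ``(z, y, x)`` with z the axis of acoustic
propagation (transducer at negative z, natural focus at the origin).  Every
physical 3-vector in this package -- voxel spacings, positions, Gaussian
widths, focus displacements -- follows the same ``(z, y, x)`` ordering, in SI
units (metres, seconds, Hz) unless a docstring says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "centered_axis",
    "PressurePlane",
    "PressureVolume",
    "SequenceConstants",
    "ComplexImageSeries",
    "TemperatureSeries",
    "DoseMap",
    "SliceStack",
]


def centered_axis(n: int, step: float) -> np.ndarray:
    """Coordinates of ``n`` samples with spacing ``step``, symmetric about 0."""
    return (np.arange(n) - (n - 1) / 2.0) * step


@dataclass
class PressurePlane:
    """Complex pressure samples on a regular 2D grid at a known axial position.

    Parameters
    ----------
    data : complex ndarray, shape (ny, nx)
        Pressure samples (arbitrary but consistent pressure units).
    spacing : float
        In-plane sample spacing in metres (isotropic).
    z_offset : float
        Signed axial position of the plane relative to the natural focus (m).
    frequency : float
        Acoustic frequency in Hz.
    sound_speed : float
        Speed of sound of the propagation medium in m/s.
    """

    data: np.ndarray
    spacing: float
    z_offset: float
    frequency: float
    sound_speed: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("PressurePlane.data must be 2D (ny, nx)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.frequency <= 0 or self.sound_speed <= 0:
            raise ValueError("frequency and sound_speed must be positive")
        if self.spacing >= self.wavelength / 2:
            raise ValueError(
                f"spacing {self.spacing:g} m >= lambda/2 = "
                f"{self.wavelength / 2:g} m: plane is spatially aliased"
            )

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.frequency

    @property
    def wavenumber(self) -> float:
        return 2 * np.pi * self.frequency / self.sound_speed

    @property
    def y(self) -> np.ndarray:
        return centered_axis(self.data.shape[0], self.spacing)

    @property
    def x(self) -> np.ndarray:
        return centered_axis(self.data.shape[1], self.spacing)


@dataclass
class PressureVolume:
    """Pressure magnitude (optionally complex) on a regular 3D grid.

    ``origin`` is the (z, y, x) coordinate of voxel ``[0, 0, 0]`` relative to
    the natural focus.
    """

    magnitude: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    complex_data: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.ndim != 3:
            raise ValueError("PressureVolume.magnitude must be 3D (nz, ny, nx)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")
        self.origin = tuple(float(o) for o in self.origin)
        if self.complex_data is not None:
            self.complex_data = np.asarray(self.complex_data, dtype=complex)
            if self.complex_data.shape != self.magnitude.shape:
                raise ValueError("complex_data shape must match magnitude")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in m^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.magnitude.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def same_grid(self, other: "PressureVolume") -> bool:
        return (
            self.magnitude.shape == other.magnitude.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SequenceConstants:
    """MR sequence constants needed for PRF thermometry.

    te is the echo time in seconds; b0 the main field in tesla; gamma the
    gyromagnetic ratio in Hz/T; alpha the PRF thermal coefficient in ppm/degC
    (signed; water is about -0.01); frame_interval the dynamic time in
    seconds.
    """

    te: float = 12e-3
    b0: float = 3.0
    gamma: float = 42.577e6
    alpha: float = -0.01
    frame_interval: float = 2.16

    def __post_init__(self) -> None:
        if self.te <= 0 or self.b0 <= 0 or self.frame_interval <= 0:
            raise ValueError("te, b0 and frame_interval must be positive")

    @property
    def rad_per_degc(self) -> float:
        """Phase change per degC of temperature rise: 2*pi*gamma*alpha*B0*TE."""
        return 2 * np.pi * self.gamma * (self.alpha * 1e-6) * self.b0 * self.te


@dataclass
class ComplexImageSeries:
    """Time series of complex 3D MR images with geometry and sequence constants.

    ``truth`` optionally carries the ground-truth temperature-change frames
    produced by the synthetic generator (degC, same shape as ``data``).
    """

    data: np.ndarray  # complex, (n_frames, nz, ny, nx)
    spacing: tuple[float, float, float]
    seq: SequenceConstants
    times: np.ndarray | None = None
    truth: np.ndarray | None = None
    baseline_frames: Sequence[int] = field(default_factory=lambda: (0,))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (n_frames, nz, ny, nx)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.times is None:
            self.times = np.arange(self.data.shape[0]) * self.seq.frame_interval
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frames must be time-ordered")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class TemperatureSeries:
    """Per-frame temperature-change maps with a validity mask.

    delta holds degC change from baseline, shape (n_frames, nz, ny, nx).
    Voxels where ``mask`` is False carry no temperature information and are
    excluded from every downstream volume statistic.
    """

    delta: np.ndarray
    baseline_temperature: float
    mask: np.ndarray | None
    spacing: tuple[float, float, float]
    frame_interval: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 4:
            raise ValueError("delta must be 4D (n_frames, nz, ny, nx)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.delta.shape[1:]:
                raise ValueError("mask shape must match a single frame")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DoseMap:
    """Per-voxel cumulative equivalent minutes at 43 degC."""

    cem43: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.cem43 = np.asarray(self.cem43, dtype=float)
        if np.any(self.cem43 < 0):
            raise ValueError("thermal dose must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SliceStack:
    """Ordered gross-pathology slices.

    masks are binary ablated-region label images (one per slice, common
    shape); pixel_scale is metres/pixel; thickness_mean / thickness_sd are
    per-slice caliper thickness and repeat-measurement spread in metres.
    area_sd optionally supplies per-slice area uncertainties (m^2); when
    absent a boundary-pixel heuristic is used.  true_volume (m^3) is filled
    by the synthetic generator.
    """

    masks: list[np.ndarray]
    pixel_scale: float
    thickness_mean: np.ndarray
    thickness_sd: np.ndarray
    area_sd: np.ndarray | None = None
    true_volume: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        self.thickness_mean = np.asarray(self.thickness_mean, dtype=float)
        self.thickness_sd = np.asarray(self.thickness_sd, dtype=float)
        n = len(self.masks)
        if self.thickness_mean.shape != (n,) or self.thickness_sd.shape != (n,):
            raise ValueError("one thickness mean/sd required per slice")
        if np.any(self.thickness_mean <= 0):
            raise ValueError("slice thicknesses must be positive")
        if np.any(self.thickness_sd < 0):
            raise ValueError("thickness sd must be nonnegative")

    def __len__(self) -> int:
        return len(self.masks)
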