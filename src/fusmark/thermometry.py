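"""PRF-shift MR thermometry and CEM43 thermal-dose accumulation.

Water proton resonance frequency falls by about 0.01 ppm per degC, so the
phase of a gradient-echo image is a thermometer: the principal-value phase
difference of each frame against a complex-averaged baseline maps linearly
to temperature change through ``dT = dphi / (2*pi*gamma*alpha*B0*TE)``.
Thermal dose is accumulated as cumulative equivalent minutes at 43 degC
(CEM43), ``sum_t R**(43 - T_t) * dt_min`` with R = 0.5 at or above 43 degC
and 0.25 below, and 240 CEM43 as the ablation threshold.

Two treatment-volume statistics are provided: the largest contiguous volume
with dose of at least 240 CEM43 (inclusive, per "at least"), and the total
-- possibly noncontiguous -- volume of voxels whose temperature rise exceeds
10 degC (strict, per "greater than"), a proxy used when experiments start
from room temperature.
"""

from __future__ import annotations

import logging

import numpy as np

from .acoustic import largest_contiguous_region
from .containers import ComplexImageSeries, DoseMap, SequenceConstants, TemperatureSeries

__all__ = [
    "phase_change",
    "prf_temperature",
    "snr_mask",
    "cem43",
    "accumulate_dose",
    "dose_volume",
    "hot_volume",
]

logger = logging.getLogger(__name__)


def phase_change(
    series: ComplexImageSeries,
    baseline_frames=None,
) -> np.ndarray:
    """Principal-value phase difference of each frame against the baseline.

    The baseline is the complex mean of the given frames (defaults to the
    series' own pre-heating frames); the returned per-frame maps are
    ``angle(frame * conj(baseline))`` in (-pi, pi].  No temporal unwrapping
    is applied -- at a ~2 s dynamic time the per-frame phase change is far
    below pi -- but a warning is logged if any frame-to-frame step exceeds
    pi/2, the regime where wrapping against a fixed baseline becomes a risk.
    """
    if baseline_frames is None:
        baseline_frames = series.baseline_frames
    baseline_frames = tuple(int(i) for i in np.atleast_1d(baseline_frames))
    if len(baseline_frames) == 0:
        raise ValueError("baseline frame set must be nonempty")
    baseline = series.data[list(baseline_frames)].mean(axis=0)
    dphi = np.angle(series.data * np.conj(baseline)[None])
    # wrap-risk heuristic on signal-carrying voxels only (background phase is
    # uniformly random and always produces pi-sized steps)
    mean_mag = np.abs(series.data).mean(axis=0)
    signal = mean_mag > 0.5 * mean_mag.max()
    steps = np.abs(np.diff(dphi[:, signal], axis=0))
    steps = np.minimum(steps, 2 * np.pi - steps)
    if steps.size and steps.max() > np.pi / 2:
        logger.warning(
            "frame-to-frame phase step up to %.2f rad exceeds pi/2; "
            "phase wrapping against the fixed baseline is possible",
            float(steps.max()),
        )
    return dphi


def prf_temperature(
    phase_maps: np.ndarray,
    seq: SequenceConstants,
    baseline_temperature: float = 20.0,
    spacing: tuple[float, float, float] = (1e-3, 1e-3, 1e-3),
    mask: np.ndarray | None = None,
    sign: float = 1.0,
) -> TemperatureSeries:
    """Convert phase-difference maps to a temperature-change series.

    ``sign`` (+1 default) flips the convention for scanners that report the
    opposite phase polarity.  Raises if the PRF coefficient alpha is zero.
    """
    if seq.alpha == 0:
        raise ValueError("alpha must be nonzero for PRF thermometry")
    delta = sign * np.asarray(phase_maps, dtype=float) / seq.rad_per_degc
    return TemperatureSeries(
        delta=delta,
        baseline_temperature=baseline_temperature,
        mask=mask,
        spacing=spacing,
        frame_interval=seq.frame_interval,
    )


def snr_mask(
    series: ComplexImageSeries,
    noise_region: np.ndarray,
    k: float = 5.0,
) -> np.ndarray:
    """Voxels whose time-mean magnitude exceeds ``k`` noise standard deviations.

    The per-channel noise sigma is estimated from the real and imaginary
    parts of all frames over ``noise_region``.  The comparison is strictly
    greater-than: a voxel at exactly ``k * sigma`` is excluded.
    """
    noise_region = np.asarray(noise_region, dtype=bool)
    if not noise_region.any():
        raise ValueError("noise region must be nonempty")
    samples = series.data[:, noise_region]
    sigma = float(np.concatenate([samples.real.ravel(), samples.imag.ravel()]).std())
    if sigma == 0:
        raise ValueError("noise region has zero variance; cannot estimate sigma")
    mean_mag = np.abs(series.data).mean(axis=0)
    return mean_mag > k * sigma


def cem43(temps: TemperatureSeries) -> DoseMap:
    """Accumulate cumulative equivalent minutes at 43 degC over all frames.

    Each frame contributes ``R**(43 - T) * dt`` with dt the frame interval
    in minutes and T the absolute temperature (baseline + dT); R is 0.5 for
    T >= 43 degC and 0.25 below.  Masked voxels accumulate zero dose;
    non-finite temperatures outside the mask raise.
    """
    T = temps.baseline_temperature + temps.delta
    if temps.mask is not None:
        valid = temps.mask
        if not np.isfinite(T[:, valid]).all():
            raise ValueError("non-finite temperature in unmasked voxels")
    else:
        valid = np.ones(temps.delta.shape[1:], dtype=bool)
        if not np.isfinite(T).all():
            raise ValueError("non-finite temperature in unmasked voxels")
    dt_min = temps.frame_interval / 60.0
    R = np.where(T >= 43.0, 0.5, 0.25)
    dose = (R ** (43.0 - T) * dt_min).sum(axis=0)
    dose = np.where(valid, dose, 0.0)
    return DoseMap(cem43=dose, spacing=temps.spacing)


def accumulate_dose(*doses: DoseMap) -> DoseMap:
    """Sum dose maps from consecutive sonications (dose is additive)."""
    if not doses:
        raise ValueError("at least one dose map required")
    first = doses[0]
    total = np.zeros_like(first.cem43)
    for d in doses:
        if d.cem43.shape != first.cem43.shape or not np.allclose(
            d.spacing, first.spacing
        ):
            raise ValueError("dose maps must share a grid")
        total = total + d.cem43
    return DoseMap(cem43=total, spacing=first.spacing)


def dose_volume(
    dose: DoseMap,
    threshold: float = 240.0,
    connectivity: int = 1,
) -> tuple[np.ndarray, float]:
    """Largest contiguous volume with dose of at least ``threshold`` CEM43.

    Returns ``(mask, volume_cm3)``.  The threshold is inclusive.
    """
    mask, vol_m3 = largest_contiguous_region(
        dose.cem43, threshold, dose.spacing, connectivity=connectivity, strict=False
    )
    return mask, vol_m3 * 1e6


def hot_volume(
    temps: TemperatureSeries,
    delta_threshold: float = 10.0,
    roi: np.ndarray | None = None,
    per_frame: bool = False,
) -> float | np.ndarray:
    """Total volume (cm^3) of voxels with temperature rise above threshold.

    No contiguity is required: disjoint hot regions all count, in contrast
    to the dose volume.  The comparison is strict.  By default the temporal
    maximum of dT decides; ``per_frame=True`` instead returns one volume per
    frame.  Voxels outside ``roi`` or the series' validity mask never count.
    """
    keep = np.ones(temps.delta.shape[1:], dtype=bool)
    if roi is not None:
        keep &= np.asarray(roi, dtype=bool)
    if temps.mask is not None:
        keep &= temps.mask
    vox_cm3 = temps.voxel_volume * 1e6
    if per_frame:
        hot = (temps.delta > delta_threshold) & keep[None]
        return hot.sum(axis=(1, 2, 3)) * vox_cm3
    hot = (temps.delta.max(axis=0) > delta_threshold) & keep
    return float(hot.sum()) * vox_cm3
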