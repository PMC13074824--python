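"""File I/O: HDF5 pressure planes, NIfTI volumes/series, slice-stack folders.

Pressure planes live in a small HDF5 container (named real/imag arrays plus
grid metadata attributes); volumes and image series are written as NIfTI
with a JSON sidecar for sequence constants; gross slice stacks are a folder
of PNG masks plus a CSV of per-slice thicknesses.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .containers import (
    ComplexImageSeries,
    PressurePlane,
    PressureVolume,
    SequenceConstants,
    SliceStack,
)

__all__ = [
    "save_pressure_plane",
    "load_pressure_plane",
    "export_magnitude_csv",
    "save_volume_nifti",
    "save_series_nifti",
    "load_series_nifti",
    "save_slice_stack",
    "load_slice_stack",
]


def save_pressure_plane(path, plane: PressurePlane) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=plane.data.real)
        f.create_dataset("imag", data=plane.data.imag)
        f.attrs["spacing"] = plane.spacing
        f.attrs["z_offset"] = plane.z_offset
        f.attrs["frequency"] = plane.frequency
        f.attrs["sound_speed"] = plane.sound_speed


def load_pressure_plane(path) -> PressurePlane:
    with h5py.File(path, "r") as f:
        data = f["real"][()] + 1j * f["imag"][()]
        return PressurePlane(
            data=data,
            spacing=float(f.attrs["spacing"]),
            z_offset=float(f.attrs["z_offset"]),
            frequency=float(f.attrs["frequency"]),
            sound_speed=float(f.attrs["sound_speed"]),
        )


def export_magnitude_csv(path, plane: PressurePlane) -> None:
    """Magnitude of a plane as CSV for quick inspection (rows = y, cols = x)."""
    np.savetxt(path, np.abs(plane.data), delimiter=",", fmt="%.9g")


def _affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """NIfTI affine in mm from (z, y, x) spacing/origin; array axes map x<->2."""
    aff = np.diag([spacing[2] * 1e3, spacing[1] * 1e3, spacing[0] * 1e3, 1.0])
    aff[:3, 3] = [origin[2] * 1e3, origin[1] * 1e3, origin[0] * 1e3]
    return aff


def save_volume_nifti(path, volume: PressureVolume) -> None:
    # nibabel expects (x, y, z) ordering on disk
    img = nib.Nifti1Image(
        volume.magnitude.transpose(2, 1, 0), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def save_series_nifti(stem, series: ComplexImageSeries) -> None:
    """Write a series as <stem>_mag.nii.gz, <stem>_phase.nii.gz, <stem>.json."""
    stem = Path(stem)
    aff = _affine(series.spacing)
    mag = np.abs(series.data).transpose(3, 2, 1, 0)  # (x, y, z, t)
    phase = np.angle(series.data).transpose(3, 2, 1, 0)
    nib.save(nib.Nifti1Image(mag, aff), str(stem) + "_mag.nii.gz")
    nib.save(nib.Nifti1Image(phase, aff), str(stem) + "_phase.nii.gz")
    sidecar = {
        "te": series.seq.te,
        "b0": series.seq.b0,
        "gamma": series.seq.gamma,
        "alpha": series.seq.alpha,
        "frame_interval": series.seq.frame_interval,
        "spacing": list(series.spacing),
        "times": [float(t) for t in series.times],
        "baseline_frames": [int(i) for i in series.baseline_frames],
    }
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_series_nifti(stem) -> ComplexImageSeries:
    stem = Path(stem)
    meta = json.loads(Path(str(stem) + ".json").read_text())
    mag = np.asarray(nib.load(str(stem) + "_mag.nii.gz").dataobj)
    phase = np.asarray(nib.load(str(stem) + "_phase.nii.gz").dataobj)
    data = (mag * np.exp(1j * phase)).transpose(3, 2, 1, 0)
    seq = SequenceConstants(
        te=meta["te"],
        b0=meta["b0"],
        gamma=meta["gamma"],
        alpha=meta["alpha"],
        frame_interval=meta["frame_interval"],
    )
    return ComplexImageSeries(
        data=data,
        spacing=tuple(meta["spacing"]),
        seq=seq,
        times=np.asarray(meta["times"]),
        baseline_frames=tuple(meta["baseline_frames"]),
    )


def save_slice_stack(directory, stack: SliceStack) -> None:
    """PNG mask per slice plus slices.csv with scale and thicknesses."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, mask in enumerate(stack.masks):
        name = f"slice_{i:03d}.png"
        iio.imwrite(directory / name, (mask.astype(np.uint8) * 255))
        rows.append(
            {
                "slice_id": i,
                "mask_file": name,
                "pixel_scale_m": stack.pixel_scale,
                "thickness_mean_m": stack.thickness_mean[i],
                "thickness_sd_m": stack.thickness_sd[i],
            }
        )
    pd.DataFrame(rows).to_csv(directory / "slices.csv", index=False)


def load_slice_stack(directory) -> SliceStack:
    directory = Path(directory)
    table = pd.read_csv(directory / "slices.csv").sort_values("slice_id")
    masks = [iio.imread(directory / f) > 127 for f in table["mask_file"]]
    return SliceStack(
        masks=masks,
        pixel_scale=float(table["pixel_scale_m"].iloc[0]),
        thickness_mean=table["thickness_mean_m"].to_numpy(),
        thickness_sd=table["thickness_sd_m"].to_numpy(),
    )
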