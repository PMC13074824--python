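"""End-to-end synthetic marker-vs-control experiments.

Two orchestrated experiment kinds mirror the study design: an acoustic
experiment that places an occluding marker screen at six positions relative
to the natural focus (in-plane and 7 mm far-field; centered and 3 mm
lateral along each transverse axis), reconstructs marker and control
volumes, and tabulates focus metrics; and a thermometry experiment that
runs a sonication schedule through the MR forward model twice -- once with
the marker's dipole field, signal void and optional temperature-dependent
susceptibility, once without -- and tabulates peak temperature rise, hot
volume and thermal-dose volume per arm.

Configs use millimetres for lengths (converted to SI at this boundary) and
explicit seeds; every run writes a manifest (config hash, seeds, package
version) sufficient to reproduce its outputs byte-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustic import focus_metrics, project_plane
from .containers import SequenceConstants
from .synthetic import (
    HeatingModel,
    MarkerFieldModel,
    OcclusionScreen,
    TransducerGeometry,
    simulate_bowl_plane,
    simulate_mrti_series,
)
from .thermometry import (
    accumulate_dose,
    cem43,
    dose_volume,
    hot_volume,
    phase_change,
    prf_temperature,
    snr_mask,
)

__all__ = [
    "AcousticExperimentConfig",
    "ThermometryExperimentConfig",
    "ExperimentConfig",
    "run_acoustic_experiment",
    "run_thermometry_experiment",
    "run_experiment",
    "write_manifest",
]


@dataclass
class AcousticExperimentConfig:
    """Marker-vs-control hydrophone-scan experiment; lengths in mm."""

    n: int = 41
    spacing_mm: float = 0.5
    z_range_mm: tuple[float, float] = (-20.0, 20.0)
    z_step_mm: float = 0.5
    pad_factor: int = 2
    # six marker positions: axial planes x transverse offsets (x_mm, y_mm)
    marker_planes_mm: tuple[float, ...] = (0.0, 7.0)
    lateral_offsets_mm: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (3.0, 0.0),
        (0.0, 3.0),
    )
    measurement_gap_mm: float = 1.0
    marker_radius_mm: float = 1.5
    amplitude_transmission: float = 0.3
    phase_shift: float = 0.5
    marker_enabled: bool = True
    noise_sd: float = 0.0
    focal_length_mm: float = 130.0
    aperture_mm: float = 154.0
    frequency_hz: float = 1.0e6
    sound_speed: float = 1482.0
    source_points: int = 40000


@dataclass
class ThermometryExperimentConfig:
    """Marker-vs-control sonication schedule through the MR forward model."""

    shape: tuple[int, int, int] = (24, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_frames: int = 12
    frame_interval_s: float = 2.16
    n_baseline_frames: int = 2
    # (acoustic watts, seconds) per sonication; the study's single-point shots
    sonications: tuple[tuple[float, float], ...] = ((24.0, 21.0), (24.0, 21.0))
    degc_per_watt: float = 0.75
    sigma_mm: tuple[float, float, float] = (4.0, 1.5, 1.5)
    target_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thermal_diffusivity_mm2_s: float = 0.143
    baseline_temperature_c: float = 21.0
    snr: float | None = 50.0
    snr_mask_k: float = 5.0
    te_ms: float = 12.0
    b0_t: float = 3.0
    marker_enabled: bool = True
    marker_position_mm: tuple[float, float, float] = (0.0, 4.0, 0.0)
    dipole_scale: float = 2e-9
    void_radius_mm: float = 3.0
    susceptibility_temp_coefficient: float = 0.0


@dataclass
class ExperimentConfig:
    kind: str = "acoustic"
    seed: int = 0
    acoustic: AcousticExperimentConfig = field(default_factory=AcousticExperimentConfig)
    thermometry: ThermometryExperimentConfig = field(
        default_factory=ThermometryExperimentConfig
    )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def build(klass, sub):
            kwargs = {}
            names = {f.name for f in dataclasses.fields(klass)}
            for key, val in (sub or {}).items():
                if key not in names:
                    raise ValueError(f"unknown config key {key!r} for {klass.__name__}")
                if isinstance(val, list):
                    val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
                kwargs[key] = val
            return klass(**kwargs)

        return cls(
            kind=d.get("kind", "acoustic"),
            seed=int(d.get("seed", 0)),
            acoustic=build(AcousticExperimentConfig, d.get("acoustic")),
            thermometry=build(ThermometryExperimentConfig, d.get("thermometry")),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(out_dir, cfg: ExperimentConfig, outputs: list[str]) -> Path:
    """Deterministic reproduction manifest (no timestamps by design)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "fusmark",
        "version": __version__,
        "kind": cfg.kind,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.to_dict(),
        "outputs": sorted(outputs),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path


def _write_table(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def run_acoustic_experiment(
    cfg: AcousticExperimentConfig,
    seed: int = 0,
    out_dir=None,
) -> pd.DataFrame:
    """Run the six-position marker-vs-control acoustic experiment.

    For each marker position the marker and control scan planes share a
    noise seed, both are projected into the reconstruction volume, and the
    focus metrics of the marker volume against its paired control are
    emitted as one table row.  Control outputs never depend on any marker
    parameter.
    """
    mm = 1e-3
    geom = TransducerGeometry(
        focal_length=cfg.focal_length_mm * mm,
        aperture_diameter=cfg.aperture_mm * mm,
        frequency=cfg.frequency_hz,
        medium_sound_speed=cfg.sound_speed,
        source_discretization=cfg.source_points,
    )
    z0, z1 = cfg.z_range_mm
    n_z = int(round((z1 - z0) / cfg.z_step_mm)) + 1
    z_targets = (z0 + np.arange(n_z) * cfg.z_step_mm) * mm

    rows = []
    control_cache: dict[float, object] = {}
    for i, plane_mm in enumerate(cfg.marker_planes_mm):
        z_meas = (plane_mm + cfg.measurement_gap_mm) * mm
        for j, (ox_mm, oy_mm) in enumerate(cfg.lateral_offsets_mm):
            pos_seed = seed * 1000 + i * 10 + j
            if z_meas not in control_cache:
                control_cache[z_meas] = simulate_bowl_plane(
                    geom,
                    n=cfg.n,
                    spacing=cfg.spacing_mm * mm,
                    z_offset=z_meas,
                    noise_sd=cfg.noise_sd,
                    seed=pos_seed,
                )
            control_plane = control_cache[z_meas]
            if cfg.marker_enabled:
                screen = OcclusionScreen(
                    plane_offset=plane_mm * mm,
                    center_offset=(oy_mm * mm, ox_mm * mm),
                    radius=cfg.marker_radius_mm * mm,
                    amplitude_transmission=cfg.amplitude_transmission,
                    phase_shift=cfg.phase_shift,
                )
            else:
                screen = None
            test_plane = simulate_bowl_plane(
                geom,
                n=cfg.n,
                spacing=cfg.spacing_mm * mm,
                z_offset=z_meas,
                screen=screen,
                noise_sd=cfg.noise_sd,
                seed=pos_seed,
            )
            vol_test = project_plane(test_plane, z_targets, cfg.pad_factor)
            vol_ctrl = project_plane(control_plane, z_targets, cfg.pad_factor)
            m = focus_metrics(vol_test, vol_ctrl)
            rows.append(
                {
                    "marker_plane_mm": plane_mm,
                    "offset_x_mm": ox_mm,
                    "offset_y_mm": oy_mm,
                    "peak_change_fraction": m.peak_change_vs_control,
                    "focus_volume_mm3": m.focus_volume * 1e9,
                    "focus_volume_change_fraction": m.focus_volume_change,
                    "displacement_x_mm": m.displacement_vector[2] * 1e3,
                    "displacement_y_mm": m.displacement_vector[1] * 1e3,
                    "displacement_z_mm": m.displacement_vector[0] * 1e3,
                    "displacement_total_mm": m.displacement_total * 1e3,
                    "insertion_loss_db": m.insertion_loss,
                }
            )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        _write_table(df, Path(out_dir) / "acoustic_metrics.csv")
    return df


def run_thermometry_experiment(
    cfg: ThermometryExperimentConfig,
    seed: int = 0,
    out_dir=None,
) -> pd.DataFrame:
    """Run the sonication schedule through marker and control arms.

    Each sonication is one simulated MRTI acquisition; the two arms share
    the same heating and noise seed and differ only in the presence of the
    marker model.  Per-sonication rows report masked peak temperature rise
    and hot volume; the thermal-dose volume is computed from the dose map
    accumulated over all sonications of the arm (dose is additive) and
    reported on each row under ``cumulative_dose_volume_cm3``.
    """
    mm = 1e-3
    spacing = tuple(s * mm for s in cfg.spacing_mm)
    seq = SequenceConstants(
        te=cfg.te_ms * 1e-3,
        b0=cfg.b0_t,
        frame_interval=cfg.frame_interval_s,
    )
    deposit_time = cfg.n_baseline_frames * cfg.frame_interval_s
    marker = (
        MarkerFieldModel(
            dipole_moment_scale=cfg.dipole_scale,
            position=tuple(p * mm for p in cfg.marker_position_mm),
            void_radius=cfg.void_radius_mm * mm,
            susceptibility_temp_coefficient=cfg.susceptibility_temp_coefficient,
        )
        if cfg.marker_enabled
        else None
    )

    support = _phantom_support(cfg.shape)
    background = ~support

    rows = []
    for arm, arm_marker in (("control", None), ("marker", marker)):
        doses = []
        arm_rows = []
        for s_idx, (power_w, duration_s) in enumerate(cfg.sonications):
            peak_dt = power_w * cfg.degc_per_watt
            heating = (
                HeatingModel(
                    peak_delta_t=peak_dt,
                    sigma=tuple(s * mm for s in cfg.sigma_mm),
                    deposit_time=deposit_time,
                    thermal_diffusivity=cfg.thermal_diffusivity_mm2_s * 1e-6,
                    center=tuple(p * mm for p in cfg.target_mm),
                )
                if peak_dt > 0
                else None
            )
            series = simulate_mrti_series(
                shape=cfg.shape,
                spacing=spacing,
                n_frames=cfg.n_frames,
                frame_interval=cfg.frame_interval_s,
                heating=heating,
                marker=arm_marker,
                snr=cfg.snr,
                seq=seq,
                seed=seed * 100 + s_idx,  # shared across arms by design
                support=support,
            )
            if cfg.snr is not None:
                mask = snr_mask(series, background, k=cfg.snr_mask_k)
            else:
                mask = support
            dphi = phase_change(series)
            temps = prf_temperature(
                dphi,
                seq,
                baseline_temperature=cfg.baseline_temperature_c,
                spacing=spacing,
                mask=mask,
            )
            dose = cem43(temps)
            doses.append(dose)
            peak = float(temps.delta[:, mask].max()) if mask.any() else 0.0
            arm_rows.append(
                {
                    "arm": arm,
                    "sonication": s_idx,
                    "power_w": power_w,
                    "duration_s": duration_s,
                    "peak_delta_t_c": peak,
                    "hot_volume_cm3": hot_volume(temps, roi=support),
                    "dose_volume_cm3": dose_volume(dose)[1],
                }
            )
        total = accumulate_dose(*doses)
        cum_vol = dose_volume(total)[1]
        for r in arm_rows:
            r["cumulative_dose_volume_cm3"] = cum_vol
        rows.extend(arm_rows)

    df = pd.DataFrame(rows)
    if out_dir is not None:
        _write_table(df, Path(out_dir) / "thermometry_metrics.csv")
    return df


def _phantom_support(shape: tuple[int, int, int]) -> np.ndarray:
    """Cylindrical phantom support inside the FOV (radius 0.8 x half-extent)."""
    nz, ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2
    x = np.arange(nx) - (nx - 1) / 2
    r = np.hypot(y[:, None], x[None, :])
    disk = r <= 0.8 * min((ny - 1) / 2, (nx - 1) / 2)
    return np.broadcast_to(disk[None], shape).copy()


def run_experiment(cfg: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Dispatch on config kind, write the metrics table and manifest."""
    out_dir = Path(out_dir)
    if cfg.kind == "acoustic":
        df = run_acoustic_experiment(cfg.acoustic, seed=cfg.seed, out_dir=out_dir)
        outputs = ["acoustic_metrics.csv"]
    elif cfg.kind == "thermometry":
        df = run_thermometry_experiment(cfg.thermometry, seed=cfg.seed, out_dir=out_dir)
        outputs = ["thermometry_metrics.csv"]
    else:
        raise ValueError(f"unknown experiment kind {cfg.kind!r}")
    write_manifest(out_dir, cfg, outputs)
    return df
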