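"""Synthetic-physics generators with known ground truth for every stage.

The generators emulate the study conditions of a breast-marker MRgFUS
experiment: a 1 MHz spherically focused bowl (13 cm focal length, 15.4 cm
aperture) scanned by a hydrophone in 41x41, 0.5 mm planes; 3 T PRF
thermometry of Gaussian focal heating diffusing in gelatin (thermal
diffusivity 0.143 mm^2/s) with point-dipole marker phase artifacts and a
signal void; serial ~1.5 mm gross slices of an ablated (ellipsoidal) region;
and cylindrical phantom magnitude images with a spherical void.

Each generator is deterministic under a fixed seed and returns the ground
truth needed to verify the downstream stage that consumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acoustic import angular_spectrum_propagate
from .containers import (
    ComplexImageSeries,
    PressurePlane,
    SequenceConstants,
    SliceStack,
    centered_axis,
)

__all__ = [
    "TransducerGeometry",
    "OcclusionScreen",
    "HeatingModel",
    "MarkerFieldModel",
    "bowl_quadrature",
    "rayleigh_field",
    "simulate_bowl_plane",
    "heat_kernel_delta_t",
    "simulate_mrti_series",
    "simulate_slice_stack",
    "simulate_phantom_image",
]

#: Density of water (kg/m^3); sets the pressure scale of the Rayleigh integral
#: for a unit normal surface velocity.
RHO_WATER = 1000.0


@dataclass(frozen=True)
class TransducerGeometry:
    """Spherically focused bowl source.

    Defaults are the study transducer: 1 MHz, 13 cm focal length (radius of
    curvature), 15.4 cm aperture, driven in water at 20 degC (c = 1482 m/s).
    ``source_discretization`` is the approximate number of surface elements
    used for the numeric Rayleigh integral.
    """

    focal_length: float = 0.13
    aperture_diameter: float = 0.154
    frequency: float = 1.0e6
    medium_sound_speed: float = 1482.0
    source_discretization: int = 40000

    def __post_init__(self) -> None:
        if not (self.focal_length > self.aperture_diameter / 2 > 0):
            raise ValueError("require focal_length > aperture_diameter/2 > 0")
        if self.frequency <= 0 or self.medium_sound_speed <= 0:
            raise ValueError("frequency and sound speed must be positive")
        if self.source_discretization < 16:
            raise ValueError("source_discretization too small")

    @property
    def wavelength(self) -> float:
        return self.medium_sound_speed / self.frequency

    @property
    def wavenumber(self) -> float:
        return 2 * np.pi / self.wavelength

    @property
    def half_angle(self) -> float:
        """Aperture half-angle subtended at the centre of curvature (rad)."""
        return math.asin(self.aperture_diameter / 2 / self.focal_length)


@dataclass(frozen=True)
class OcclusionScreen:
    """Thin complex-transmission screen standing in for a biopsy marker.

    The marker is modeled acoustically as a circular patch that multiplies
    the incident field by ``amplitude_transmission * exp(i*phase_shift)``
    inside ``radius``; outside the patch the field passes unchanged.  Full
    scattering is deliberately out of scope -- the screen reproduces the
    occlusion/diffraction phenomenology that downstream metrics respond to.

    plane_offset is the signed axial position of the screen relative to the
    natural focus; center_offset is the transverse (y, x) offset in metres.
    """

    plane_offset: float = 0.0
    center_offset: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.5e-3
    amplitude_transmission: float = 0.0
    phase_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")
        if not 0 <= self.amplitude_transmission <= 1:
            raise ValueError("amplitude_transmission must lie in [0, 1]")


@dataclass(frozen=True)
class HeatingModel:
    """Instantaneous Gaussian temperature deposit evolving by heat diffusion.

    A deposit of peak ``peak_delta_t`` degC with per-axis widths ``sigma``
    (z, y, x; metres) is placed at ``center`` at time ``deposit_time`` and
    spreads with thermal diffusivity ``thermal_diffusivity`` (m^2/s; the
    gelatin phantom value 0.143 mm^2/s by default).
    """

    peak_delta_t: float = 18.0
    sigma: tuple[float, float, float] = (4e-3, 1.5e-3, 1.5e-3)
    deposit_time: float = 4.32
    thermal_diffusivity: float = 0.143e-6
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.peak_delta_t < 0:
            raise ValueError("peak_delta_t must be nonnegative")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("all sigma must be positive")
        if self.thermal_diffusivity < 0:
            raise ValueError("thermal_diffusivity must be nonnegative")


@dataclass(frozen=True)
class MarkerFieldModel:
    """Point-dipole susceptibility field and signal void of a metallic marker.

    The static phase artifact follows the far-field point-dipole angular form
    ``A * (3*cos^2(theta) - 1) / r^3`` with a single amplitude constant
    ``dipole_moment_scale`` (rad*m^3) rather than SI susceptibility
    constants; downstream code needs a realistic spatial pattern, not
    device-specific field maps.  ``susceptibility_temp_coefficient`` scales
    the dipole amplitude by ``(1 + coeff * dT_marker)`` as the marker heats,
    emulating temperature-dependent susceptibility.  Magnitude is zeroed
    within ``void_radius`` of the marker with a one-voxel smooth roll-off.
    """

    dipole_moment_scale: float = 2e-9
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b0_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    void_radius: float = 3e-3
    susceptibility_temp_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.void_radius < 0:
            raise ValueError("void_radius must be nonnegative")
        if not np.isclose(np.linalg.norm(self.b0_axis), 1.0):
            raise ValueError("b0_axis must have unit norm")


# ---------------------------------------------------------------------------
# Acoustic generator


def bowl_quadrature(geom: TransducerGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic equal-area midpoint quadrature over the spherical cap.

    Returns (points (N, 3) in (z, y, x) with the focus at the origin,
    weights (N,) in m^2).  The cap is sampled on a midpoint product grid in
    (cos(theta), phi), which is exactly equal-area on the sphere; phi count
    is forced even so the point set is symmetric under x -> -x and y -> -y.
    """
    n = geom.source_discretization
    u_min = math.cos(geom.half_angle)
    n_theta = max(4, int(round(math.sqrt(n / 4))))
    n_phi = max(8, 2 * int(round(n / n_theta / 2)))

    du = (1.0 - u_min) / n_theta
    dphi = 2 * np.pi / n_phi
    u = u_min + (np.arange(n_theta) + 0.5) * du
    phi = (np.arange(n_phi) + 0.5) * dphi

    sin_t = np.sqrt(1.0 - u**2)
    F = geom.focal_length
    z = -F * u
    x = F * sin_t[:, None] * np.cos(phi)[None, :]
    y = F * sin_t[:, None] * np.sin(phi)[None, :]
    zz = np.broadcast_to(z[:, None], x.shape)
    points = np.stack(
        [zz.ravel(), y.ravel(), x.ravel()], axis=1
    )
    weights = np.full(points.shape[0], F**2 * du * dphi)
    return points, weights


def rayleigh_field(
    geom: TransducerGeometry,
    targets: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Rayleigh-integral pressure at arbitrary field points.

    ``targets`` is (N, 3) in (z, y, x) metres relative to the natural focus.
    The source vibrates with unit normal velocity; the prefactor
    ``-i*rho*c*k/(2*pi)`` sets the absolute pressure scale.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    points, weights = bowl_quadrature(geom)
    k = geom.wavenumber
    pref = -1j * RHO_WATER * geom.medium_sound_speed * k / (2 * np.pi)
    out = np.empty(targets.shape[0], dtype=complex)
    for start in range(0, targets.shape[0], chunk):
        t = targets[start : start + chunk]
        diff = t[:, None, :] - points[None, :, :]
        R = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        out[start : start + chunk] = (np.exp(1j * k * R) / R) @ weights
    return pref * out


def _plane_targets(n: int, spacing: float, z: float) -> np.ndarray:
    yy = centered_axis(n, spacing)
    xx = centered_axis(n, spacing)
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    return np.stack([np.full(Y.size, z), Y.ravel(), X.ravel()], axis=1)


def simulate_bowl_plane(
    geom: TransducerGeometry,
    n: int = 41,
    spacing: float = 0.5e-3,
    z_offset: float = 0.0,
    screen: OcclusionScreen | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PressurePlane:
    """Simulate a hydrophone-style scan plane of the focused bowl.

    Without a screen the plane is a direct Rayleigh-integral evaluation.
    With a screen, the source field is evaluated on the screen plane (on a
    grid roughly twice the scan window), multiplied by the screen's complex
    transmission inside its radius, then angular-spectrum propagated to the
    measurement plane.  Measurement noise is independent complex Gaussian
    per sample with standard deviation ``noise_sd`` per channel.
    """
    lam = geom.wavelength
    if spacing >= lam / 2:
        raise ValueError(
            f"grid spacing {spacing:g} m >= lambda/2 = {lam / 2:g} m (aliasing)"
        )
    if abs(z_offset) > 0.05:
        raise ValueError("z_offset must be within +/-0.05 m of the natural focus")

    if screen is None:
        p = rayleigh_field(geom, _plane_targets(n, spacing, z_offset))
        p = p.reshape(n, n)
    else:
        if screen.plane_offset > z_offset:
            raise ValueError(
                "screen plane lies beyond the measurement plane along the "
                "propagation direction"
            )
        n_big = 2 * n + 1  # odd, symmetric grid covering twice the window
        p_screen = rayleigh_field(
            geom, _plane_targets(n_big, spacing, screen.plane_offset)
        ).reshape(n_big, n_big)
        yy = centered_axis(n_big, spacing)
        Y, X = np.meshgrid(yy, yy, indexing="ij")
        r = np.hypot(Y - screen.center_offset[0], X - screen.center_offset[1])
        trans = np.ones_like(p_screen)
        inside = r <= screen.radius
        trans[inside] = screen.amplitude_transmission * np.exp(
            1j * screen.phase_shift
        )
        p_big = angular_spectrum_propagate(
            p_screen * trans,
            spacing,
            geom.wavenumber,
            z_offset - screen.plane_offset,
            pad_factor=2,
        )
        lo = (n_big - n) // 2
        p = p_big[lo : lo + n, lo : lo + n]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + noise_sd * (
            rng.standard_normal(p.shape) + 1j * rng.standard_normal(p.shape)
        )
    return PressurePlane(
        data=p,
        spacing=spacing,
        z_offset=z_offset,
        frequency=geom.frequency,
        sound_speed=geom.medium_sound_speed,
    )


# ---------------------------------------------------------------------------
# MR thermometry generator


def heat_kernel_delta_t(
    heating: HeatingModel,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    tau: float,
) -> np.ndarray:
    """Closed-form diffusion of a Gaussian deposit, ``tau`` seconds after it.

    dT(r, tau) = peak * prod_a sqrt(sigma_a^2 / (sigma_a^2 + 2*D*tau))
                      * exp(-sum_a (r_a - c_a)^2 / (2*(sigma_a^2 + 2*D*tau)))
    """
    if tau < 0:
        return np.zeros(np.broadcast_shapes(*(c.shape for c in coords)))
    D = heating.thermal_diffusivity
    amp = heating.peak_delta_t
    expo = 0.0
    for c, sig, cen in zip(coords, heating.sigma, heating.center):
        s2 = sig**2 + 2 * D * tau
        amp = amp * math.sqrt(sig**2 / s2)
        expo = expo + (c - cen) ** 2 / (2 * s2)
    return amp * np.exp(-expo)


def _grid_coords(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = centered_axis(shape[0], spacing[0])[:, None, None]
    y = centered_axis(shape[1], spacing[1])[None, :, None]
    x = centered_axis(shape[2], spacing[2])[None, None, :]
    return z, y, x


def _dipole_phase(
    marker: MarkerFieldModel,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    min_r: float,
) -> np.ndarray:
    dz = coords[0] - marker.position[0]
    dy = coords[1] - marker.position[1]
    dx = coords[2] - marker.position[2]
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    r = np.maximum(r, min_r)
    bz, by, bx = marker.b0_axis
    cos_t = (dz * bz + dy * by + dx * bx) / r
    return marker.dipole_moment_scale * (3 * cos_t**2 - 1) / r**3


def simulate_mrti_series(
    shape: tuple[int, int, int] = (24, 32, 32),
    spacing: tuple[float, float, float] = (1e-3, 1e-3, 1e-3),
    n_frames: int = 8,
    frame_interval: float = 2.16,
    heating: HeatingModel | None = None,
    marker: MarkerFieldModel | None = None,
    snr: float | None = None,
    seq: SequenceConstants | None = None,
    seed: int = 0,
    support: np.ndarray | None = None,
) -> ComplexImageSeries:
    """Simulate a complex 3D MR thermometry time series.

    Frames are acquired at ``t_i = i * frame_interval``.  The ground-truth
    temperature field is the heat-kernel evolution of the heating model's
    Gaussian deposit (zero before ``deposit_time``); the image phase encodes
    it through the PRF relation ``dphi = 2*pi*gamma*alpha*B0*TE*dT`` on top
    of the marker's static dipole term, which is itself scaled by
    ``1 + susceptibility_temp_coefficient * dT(marker position)``.  Baseline
    magnitude is 1 on ``support`` (the phantom; the whole grid when None)
    and 0 outside it, with the marker's signal void carved out.  ``snr`` is
    the mean phantom magnitude over the per-channel noise standard
    deviation; ``None`` means noiseless.  The truth frames ride along on the
    returned series (``.truth``).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noiseless)")
    seq = seq or SequenceConstants(frame_interval=frame_interval)
    coords = _grid_coords(shape, spacing)
    half_extent = max(s * (n - 1) / 2 for s, n in zip(spacing, shape))
    if marker is not None and marker.void_radius > 2 * half_extent:
        raise ValueError("void_radius exceeds the grid extent")

    times = np.arange(n_frames) * frame_interval
    truth = np.zeros((n_frames,) + shape)
    if heating is not None:
        for i, t in enumerate(times):
            truth[i] = heat_kernel_delta_t(heating, coords, t - heating.deposit_time)

    if support is not None:
        support = np.asarray(support, dtype=bool)
        if support.shape != tuple(shape):
            raise ValueError("support mask shape must match the grid")
        magnitude = support.astype(float)
    else:
        magnitude = np.ones(shape)
    static_phase = np.zeros(shape)
    if marker is not None:
        dz = coords[0] - marker.position[0]
        dy = coords[1] - marker.position[1]
        dx = coords[2] - marker.position[2]
        r = np.sqrt(dz**2 + dy**2 + dx**2)
        roll = np.clip((r - marker.void_radius) / min(spacing), 0.0, 1.0)
        magnitude *= roll * roll * (3 - 2 * roll)  # smoothstep, one voxel wide
        static_phase = _dipole_phase(marker, coords, min_r=min(spacing) / 2)

    prf = seq.rad_per_degc
    data = np.empty((n_frames,) + shape, dtype=complex)
    for i, t in enumerate(times):
        phase = prf * truth[i]
        if marker is not None:
            if marker.susceptibility_temp_coefficient != 0.0 and heating is not None:
                dt_marker = float(
                    heat_kernel_delta_t(
                        heating,
                        tuple(np.asarray([p]) for p in marker.position),
                        t - heating.deposit_time,
                    )[0]
                )
                scale = 1.0 + marker.susceptibility_temp_coefficient * dt_marker
            else:
                scale = 1.0
            phase = phase + static_phase * scale
        data[i] = magnitude * np.exp(1j * phase)

    if snr is not None:
        rng = np.random.default_rng(seed)
        phantom = magnitude > 0
        sd = float(magnitude[phantom].mean()) / snr if phantom.any() else 1.0 / snr
        data += sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    onset = heating.deposit_time if heating is not None else np.inf
    baseline = tuple(int(i) for i in np.nonzero(times < onset)[0]) or (0,)
    return ComplexImageSeries(
        data=data,
        spacing=spacing,
        seq=seq,
        times=times,
        truth=truth,
        baseline_frames=baseline,
    )


# ---------------------------------------------------------------------------
# Gross-pathology generator

#: Evident resolution of the Vernier calipers used for slice thicknesses (m).
CALIPER_RESOLUTION = 0.05e-3


def simulate_slice_stack(
    semi_axes: tuple[float, float, float] = (6e-3, 5e-3, 5e-3),
    slice_thickness_mean: float = 1.5e-3,
    slice_thickness_sd: float = 0.1e-3,
    pixel_scale: float = 0.1e-3,
    area_noise_fraction: float = 0.02,
    seed: int = 0,
    n_slices: int | None = None,
    center_depth: float | None = None,
) -> SliceStack:
    """Serially slice an ellipsoidal ablated region into gross-pathology masks.

    ``semi_axes`` are (depth, y, x) half-axes of the ellipsoid in metres.
    True per-slice thicknesses are drawn from N(mean, sd); each slice's mask
    is the ellipsoid cross-section at the slice's cumulative mid-depth,
    rasterized at ``pixel_scale``, with its in-plane radii jittered by a
    fraction ~ N(0, area_noise_fraction) to emulate biological irregularity.
    Recorded thicknesses are the true values quantized to the caliper
    resolution (0.05 mm); the recorded per-slice thickness spread is the
    quantization uncertainty, resolution/sqrt(12).  The ellipsoid's exact
    volume 4/3*pi*a*b*c is returned as ground truth.
    """
    c, b, a = (float(s) for s in semi_axes)  # c along slicing depth
    if min(a, b, c) <= 0:
        raise ValueError("all semi-axes must be positive")
    if slice_thickness_mean <= 0:
        raise ValueError("slice thickness mean must be positive")
    if slice_thickness_sd < 0:
        raise ValueError("thickness sd must be nonnegative")
    if pixel_scale <= 0:
        raise ValueError("pixel scale must be positive")

    rng = np.random.default_rng(seed)
    if n_slices is None:
        n_slices = int(math.ceil((2 * c + 4 * slice_thickness_mean) / slice_thickness_mean))
    true_t = slice_thickness_mean + slice_thickness_sd * rng.standard_normal(n_slices)
    true_t = np.clip(true_t, 0.2 * slice_thickness_mean, None)
    edges = np.concatenate([[0.0], np.cumsum(true_t)])
    if center_depth is None:
        # the slicer starts at an arbitrary position relative to the ablated
        # region, so the slicing phase is random; this also removes the
        # systematic Riemann-sum bias a perfectly symmetric alignment has
        center_depth = edges[-1] / 2 + (rng.uniform() - 0.5) * slice_thickness_mean
    mids = 0.5 * (edges[:-1] + edges[1:])

    half = 1.3 * max(a, b)
    npix = 2 * int(math.ceil(half / pixel_scale)) + 1
    yy = centered_axis(npix, pixel_scale)
    Y, X = np.meshgrid(yy, yy, indexing="ij")

    masks = []
    for mid in mids:
        u = (mid - center_depth) / c
        if abs(u) < 1.0:
            s = math.sqrt(1.0 - u * u)
            jitter = 1.0 + area_noise_fraction * rng.standard_normal()
            ae = max(a * s * jitter, 0.0)
            be = max(b * s * jitter, 0.0)
            if ae > 0 and be > 0:
                mask = (X / ae) ** 2 + (Y / be) ** 2 <= 1.0
            else:
                mask = np.zeros((npix, npix), dtype=bool)
        else:
            mask = np.zeros((npix, npix), dtype=bool)
        masks.append(mask)

    res = CALIPER_RESOLUTION
    measured_t = np.round(true_t / res) * res
    thickness_sd = np.full(n_slices, res / math.sqrt(12.0))
    return SliceStack(
        masks=masks,
        pixel_scale=pixel_scale,
        thickness_mean=measured_t,
        thickness_sd=thickness_sd,
        true_volume=4.0 / 3.0 * math.pi * a * b * c,
    )


# ---------------------------------------------------------------------------
# Phantom magnitude-image generator


def simulate_phantom_image(
    shape: tuple[int, int, int] = (80, 141, 141),
    spacing: tuple[float, float, float] = (1e-3, 0.5e-3, 0.5e-3),
    phantom_radius: float = 3.0e-2,
    phantom_height: float = 7.0e-2,
    void_radius: float = 5e-3,
    void_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    signal_level: float = 100.0,
    noise_mean: float = 10.0,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalar MR-style image of a cylindrical phantom with a spherical void.

    Returns ``(image, phantom_mask, noise_region_mask)``.  Phantom voxels sit
    at ``signal_level``, the spherical void and the background at the noise
    floor ``noise_mean``; Gaussian fluctuation with sd ``noise_sd`` (default
    ``noise_mean / 10``; pass 0 for a noiseless piecewise-constant image) is
    added everywhere.  The noise-region mask is a background corner block
    suitable for estimating the noise floor.
    """
    if signal_level <= 2 * noise_mean:
        raise ValueError("require signal_level > 2 * noise_mean")
    z, y, x = _grid_coords(shape, spacing)
    phantom = (np.hypot(y, x) <= phantom_radius) & (np.abs(z) <= phantom_height / 2)
    phantom = np.broadcast_to(phantom, shape).copy()

    vc = void_center
    if void_radius > 0:
        if (
            math.hypot(vc[1], vc[2]) + void_radius > phantom_radius
            or abs(vc[0]) + void_radius > phantom_height / 2
        ):
            raise ValueError("void must lie strictly inside the phantom")
        r = np.sqrt((z - vc[0]) ** 2 + (y - vc[1]) ** 2 + (x - vc[2]) ** 2)
        void = r <= void_radius
    else:
        void = np.zeros(shape, dtype=bool)

    image = np.where(phantom & ~void, signal_level, noise_mean).astype(float)
    if noise_sd is None:
        noise_sd = noise_mean / 10.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = np.clip(image + noise_sd * rng.standard_normal(shape), 0.0, None)

    corner = np.zeros(shape, dtype=bool)
    nz, ny, nx = shape
    corner[:, : max(ny // 6, 2), : max(nx // 6, 2)] = True
    noise_region = corner & ~phantom
    if not noise_region.any():
        raise ValueError("no background corner available for the noise region; "
                         "enlarge the grid relative to the phantom")
    return image, phantom, noise_region
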