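"""Generator physics: Rayleigh bowl source, heat kernel, slice stacks, phantoms."""

import math

import numpy as np
import pytest

import fusmark as fm
from _oracles import oneil_on_axis


class TestBowlSource:
    def test_focal_pressure_matches_oneil_closed_form(self, geom):
        sim = abs(fm.rayleigh_field(geom, np.array([[0.0, 0.0, 0.0]]))[0])
        ref = oneil_on_axis(geom, 0.0)
        assert abs(sim - ref) / ref < 5e-3

    @pytest.mark.parametrize("z", [-6e-3, 6e-3, 12e-3])
    def test_off_focus_axial_pressure_matches_oneil(self, geom, z):
        sim = abs(fm.rayleigh_field(geom, np.array([[z, 0.0, 0.0]]))[0])
        ref = oneil_on_axis(geom, z)
        assert abs(sim - ref) / ref < 5e-3

    def test_quadrature_convergence_halved_discretization(self, geom):
        coarse = fm.TransducerGeometry(source_discretization=20000)
        p_full = abs(fm.rayleigh_field(geom, np.array([[0.0, 0.0, 0.0]]))[0])
        p_half = abs(fm.rayleigh_field(coarse, np.array([[0.0, 0.0, 0.0]]))[0])
        assert abs(p_half - p_full) / p_full < 1e-3

    def test_unoccluded_plane_is_axisymmetric(self):
        g = fm.TransducerGeometry(source_discretization=8000)
        plane = fm.simulate_bowl_plane(g, n=21, z_offset=1e-3)
        a = np.abs(plane.data)
        assert np.abs(a - a[:, ::-1]).max() <= 1e-6 * a.max()
        assert np.abs(a - a[::-1, :]).max() <= 1e-6 * a.max()

    def test_full_aperture_occlusion_zeroes_the_field(self):
        g = fm.TransducerGeometry(source_discretization=4000)
        screen = fm.OcclusionScreen(radius=0.2, amplitude_transmission=0.0)
        plane = fm.simulate_bowl_plane(g, n=21, z_offset=1e-3, screen=screen)
        assert np.abs(plane.data).max() == 0.0

    def test_growing_prefocal_screen_never_raises_focal_peak(self):
        g = fm.TransducerGeometry(source_discretization=8000)
        peaks = []
        for radius in (0.5e-3, 1e-3, 2e-3, 4e-3, 8e-3):
            screen = fm.OcclusionScreen(
                plane_offset=-10e-3, radius=radius, amplitude_transmission=0.3
            )
            plane = fm.simulate_bowl_plane(g, n=21, z_offset=0.0, screen=screen)
            peaks.append(np.abs(plane.data).max())
        assert all(b <= a * (1 + 1e-9) for a, b in zip(peaks, peaks[1:]))

    def test_lateral_screen_offset_breaks_symmetry_on_that_axis_only(self):
        g = fm.TransducerGeometry(source_discretization=8000)
        screen = fm.OcclusionScreen(
            plane_offset=-5e-3,
            center_offset=(0.0, 2e-3),  # x offset
            radius=2e-3,
            amplitude_transmission=0.2,
        )
        a = np.abs(fm.simulate_bowl_plane(g, n=21, z_offset=0.0, screen=screen).data)
        assert np.abs(a - a[::-1, :]).max() <= 1e-6 * a.max()  # y symmetric
        assert np.abs(a - a[:, ::-1]).max() > 1e-4 * a.max()  # x broken

    def test_seed_reproducibility_and_noise_independence(self, geom):
        g = fm.TransducerGeometry(source_discretization=2000)
        kw = dict(n=11, z_offset=1e-3, noise_sd=1e5)
        a = fm.simulate_bowl_plane(g, seed=7, **kw)
        b = fm.simulate_bowl_plane(g, seed=7, **kw)
        c = fm.simulate_bowl_plane(g, seed=8, **kw)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_aliased_spacing_and_geometry_errors(self, geom):
        with pytest.raises(ValueError, match="aliasing"):
            fm.simulate_bowl_plane(geom, n=11, spacing=1e-3, z_offset=0.0)
        with pytest.raises(ValueError, match="0.05"):
            fm.simulate_bowl_plane(geom, n=11, z_offset=0.06)
        screen = fm.OcclusionScreen(plane_offset=5e-3)
        with pytest.raises(ValueError, match="measurement plane"):
            fm.simulate_bowl_plane(geom, n=11, z_offset=0.0, screen=screen)

    def test_transducer_invariants_enforced(self):
        with pytest.raises(ValueError):
            fm.TransducerGeometry(focal_length=0.05, aperture_diameter=0.154)


class TestMrtiGenerator:
    def test_diffused_peak_matches_heat_kernel_closed_form(self):
        heating = fm.HeatingModel(
            peak_delta_t=10.0,
            sigma=(1e-3, 1e-3, 1e-3),
            deposit_time=0.0,
            thermal_diffusivity=0.143e-6,
        )
        series = fm.simulate_mrti_series(
            shape=(41, 41, 41),
            spacing=(1e-3,) * 3,
            n_frames=2,
            frame_interval=10.0,
            heating=heating,
        )
        # sigma^2 + 2*D*t = 1 + 2*0.143*10 = 3.86 mm^2 per axis
        expected = 10.0 * (1.0 / 3.86) ** 1.5
        assert abs(series.truth[1].max() - expected) < 1e-9

    def test_heat_kernel_conserves_deposited_energy(self):
        heating = fm.HeatingModel(
            peak_delta_t=10.0, sigma=(1e-3,) * 3, deposit_time=0.0
        )
        series = fm.simulate_mrti_series(
            shape=(41, 41, 41),
            spacing=(1e-3,) * 3,
            n_frames=4,
            frame_interval=10.0,
            heating=heating,
        )
        integrals = series.truth.sum(axis=(1, 2, 3))
        assert np.abs(integrals / integrals[0] - 1).max() < 1e-2

    def test_no_heating_no_marker_gives_constant_phase(self):
        series = fm.simulate_mrti_series(
            shape=(9, 9, 9), n_frames=4, frame_interval=1.0
        )
        dphi = fm.phase_change(series, baseline_frames=(0,))
        assert np.abs(dphi).max() == 0.0

    def test_dipole_axial_phase_is_minus_twice_equatorial(self):
        marker = fm.MarkerFieldModel(
            dipole_moment_scale=1e-9,
            position=(0.0, 0.0, 0.0),
            b0_axis=(1.0, 0.0, 0.0),
            void_radius=0.0,
        )
        series = fm.simulate_mrti_series(
            shape=(21, 21, 21),
            spacing=(1e-3,) * 3,
            n_frames=2,
            frame_interval=1.0,
            marker=marker,
        )
        phase = np.angle(series.data[0])
        c = 10
        # (3cos^2(theta)-1) is 2 on the B0 axis and -1 in the equatorial plane
        assert phase[c + 5, c, c] == pytest.approx(-2 * phase[c, c + 5, c], rel=1e-9)
        assert phase[c + 5, c, c] == pytest.approx(-2 * phase[c, c, c + 5], rel=1e-9)

    def test_susceptibility_heating_scales_dipole_phase(self):
        heating = fm.HeatingModel(
            peak_delta_t=10.0, sigma=(2e-3,) * 3, deposit_time=1.0, center=(0, 0, 0)
        )
        base = dict(
            dipole_moment_scale=1e-10, position=(0.0, 0.0, 0.0), void_radius=1e-3
        )
        kw = dict(
            shape=(15, 15, 15),
            spacing=(1e-3,) * 3,
            n_frames=3,
            frame_interval=2.0,
            heating=heating,
        )
        static = fm.simulate_mrti_series(marker=fm.MarkerFieldModel(**base), **kw)
        coupled = fm.simulate_mrti_series(
            marker=fm.MarkerFieldModel(susceptibility_temp_coefficient=0.05, **base),
            **kw,
        )
        pre = np.abs(np.angle(coupled.data[0]) - np.angle(static.data[0])).max()
        post = np.abs(np.angle(coupled.data[2]) - np.angle(static.data[2])).max()
        assert pre == 0.0  # before the deposit the marker is at baseline
        assert post > 0.0

    def test_void_is_carved_and_grid_validation(self):
        marker = fm.MarkerFieldModel(void_radius=3e-3, position=(0, 0, 0))
        series = fm.simulate_mrti_series(
            shape=(15, 15, 15), spacing=(1e-3,) * 3, n_frames=2, marker=marker
        )
        mag = np.abs(series.data[0])
        assert mag[7, 7, 7] == 0.0
        assert mag[7, 7, 0] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="void_radius"):
            fm.simulate_mrti_series(
                shape=(9, 9, 9),
                spacing=(1e-3,) * 3,
                n_frames=2,
                marker=fm.MarkerFieldModel(void_radius=0.1),
            )
        with pytest.raises(ValueError, match="n_frames"):
            fm.simulate_mrti_series(shape=(9, 9, 9), n_frames=1)

    def test_seeded_noise_reproducible(self):
        kw = dict(shape=(9, 9, 9), n_frames=3, snr=10.0)
        a = fm.simulate_mrti_series(seed=3, **kw)
        b = fm.simulate_mrti_series(seed=3, **kw)
        assert np.array_equal(a.data, b.data)


class TestSliceStackGenerator:
    def test_sphere_stack_area_sum_near_analytic_volume(self):
        stack = fm.simulate_slice_stack(
            (5e-3, 5e-3, 5e-3),
            slice_thickness_mean=1.5e-3,
            slice_thickness_sd=0.0,
            pixel_scale=0.1e-3,
            area_noise_fraction=0.0,
            seed=0,
        )
        total = sum(
            fm.slice_area(m, stack.pixel_scale) * 1e-4 * t
            for m, t in zip(stack.masks, stack.thickness_mean)
        )
        truth = 4.0 / 3.0 * math.pi * 5e-3**3
        assert abs(total - truth) / truth < 0.05

    def test_out_of_range_ellipsoid_gives_empty_stack(self):
        stack = fm.simulate_slice_stack(
            (3e-3, 3e-3, 3e-3), center_depth=-1.0, seed=0
        )
        assert all(not m.any() for m in stack.masks)

    def test_same_seed_same_stack(self):
        a = fm.simulate_slice_stack(seed=5)
        b = fm.simulate_slice_stack(seed=5)
        assert np.array_equal(a.thickness_mean, b.thickness_mean)
        assert all(np.array_equal(x, y) for x, y in zip(a.masks, b.masks))


class TestPhantomImage:
    def test_levels_by_construction(self):
        image, phantom, noise_region = fm.simulate_phantom_image(
            shape=(40, 81, 81), phantom_radius=15e-3, phantom_height=30e-3,
            void_radius=5e-3, seed=0,
        )
        z, y, x = np.ogrid[:40, :81, :81]
        r = np.sqrt(((z - 19.5)) ** 2 + ((y - 40) * 0.5) ** 2 + ((x - 40) * 0.5) ** 2)
        core = r < 3  # well inside the void
        assert abs(image[core].mean() - 10.0) < 1.0
        shell = phantom & (r > 8) & (r < 12)
        assert abs(image[shell].mean() - 100.0) < 1.0
        assert not (noise_region & phantom).any()

    def test_noiseless_image_is_piecewise_constant(self):
        image, _, _ = fm.simulate_phantom_image(
            shape=(20, 41, 41), phantom_radius=8e-3, phantom_height=15e-3,
            void_radius=2e-3, noise_sd=0.0,
        )
        assert set(np.unique(image)) <= {10.0, 100.0}

    def test_zero_void_radius_leaves_phantom_intact(self):
        image, phantom, _ = fm.simulate_phantom_image(
            shape=(20, 41, 41), phantom_radius=8e-3, phantom_height=15e-3,
            void_radius=0.0, noise_sd=0.0,
        )
        assert (image[phantom] == 100.0).all()

    def test_void_outside_phantom_rejected(self):
        with pytest.raises(ValueError, match="inside the phantom"):
            fm.simulate_phantom_image(
                shape=(20, 41, 41), phantom_radius=8e-3, phantom_height=15e-3,
                void_radius=5e-3, void_center=(0.0, 6e-3, 0.0),
            )
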