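"""PRF thermometry, SNR masking, CEM43 dose and treatment-volume statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import fusmark as fm
from fusmark.containers import ComplexImageSeries, DoseMap, SequenceConstants, TemperatureSeries


def _series_from_phase(phases, seq=None):
    """Build a unit-magnitude series whose frames carry the given phases."""
    seq = seq or SequenceConstants(frame_interval=1.0)
    data = np.stack([np.exp(1j * p) * np.ones((3, 3, 3)) for p in phases])
    return ComplexImageSeries(data=data, spacing=(1e-3,) * 3, seq=seq)


class TestPhaseChange:
    def test_frame_equal_to_baseline_gives_zero(self):
        series = _series_from_phase([0.2, 0.2])
        assert np.abs(fm.phase_change(series, (0,))[1]).max() < 1e-15

    def test_injected_offset_recovered_exactly(self):
        series = _series_from_phase([0.0, 0.3])
        assert fm.phase_change(series, (0,))[1] == pytest.approx(0.3, abs=1e-12)

    def test_offsets_beyond_pi_wrap_to_principal_value(self):
        series = _series_from_phase([0.0, np.pi + 0.1])
        dphi = fm.phase_change(series, (0,))[1]
        assert dphi == pytest.approx(-(np.pi - 0.1), abs=1e-12)

    def test_empty_baseline_rejected(self):
        series = _series_from_phase([0.0, 0.1])
        with pytest.raises(ValueError, match="nonempty"):
            fm.phase_change(series, ())


class TestPrfTemperature:
    SEQ = SequenceConstants(te=12e-3, b0=3.0, gamma=42.577e6, alpha=-0.01,
                            frame_interval=1.0)

    def test_reference_phase_maps_to_one_degree(self):
        # 2*pi * 42.577e6 * (-0.01e-6) * 3 * 0.012 = -0.09631 rad/degC
        dphi = np.full((1, 2, 2, 2), -0.09631)
        temps = fm.prf_temperature(dphi, self.SEQ)
        assert temps.delta[0, 0, 0, 0] == pytest.approx(1.00, abs=0.01)

    def test_linearity_in_phase(self):
        dphi = np.full((1, 2, 2, 2), 0.05)
        t1 = fm.prf_temperature(dphi, self.SEQ).delta
        t2 = fm.prf_temperature(2 * dphi, self.SEQ).delta
        assert np.allclose(t2, 2 * t1)

    def test_zero_alpha_rejected(self):
        seq = SequenceConstants(alpha=0.0)
        with pytest.raises(ValueError, match="alpha"):
            fm.prf_temperature(np.zeros((1, 2, 2, 2)), seq)

    def test_noiseless_synthetic_series_recovers_truth(self):
        heating = fm.HeatingModel(
            peak_delta_t=15.0, sigma=(3e-3, 2e-3, 2e-3), deposit_time=4.0
        )
        series = fm.simulate_mrti_series(
            shape=(21, 21, 21), spacing=(1e-3,) * 3, n_frames=6,
            frame_interval=2.16, heating=heating,
        )
        temps = fm.prf_temperature(
            fm.phase_change(series), series.seq, spacing=series.spacing
        )
        assert np.abs(temps.delta - series.truth).max() < 1e-6


class TestSnrMask:
    def _series(self, snr=20.0, seed=0, shape=(10, 12, 12)):
        support = np.zeros(shape, dtype=bool)
        support[:, 2:-2, 2:-2] = True
        series = fm.simulate_mrti_series(
            shape=shape, n_frames=3, snr=snr, seed=seed, support=support
        )
        return series, support

    def test_high_signal_voxels_all_included(self):
        series, support = self._series()
        mask = fm.snr_mask(series, ~support, k=5.0)
        assert mask[support].all()
        assert not mask[~support].any()

    def test_zero_magnitude_voxels_excluded_for_any_positive_k(self):
        data = np.ones((2, 3, 3, 3), dtype=complex)
        data[:, 1, 1, 1] = 0.0
        data[:, -1, -1, -1] = [0.1, -0.1]
        noise = np.zeros((3, 3, 3), dtype=bool)
        noise[-1, -1, -1] = True
        series = ComplexImageSeries(
            data=data, spacing=(1e-3,) * 3, seq=SequenceConstants(frame_interval=1.0)
        )
        for k in (1e-6, 0.1, 5.0):
            assert not fm.snr_mask(series, noise, k=k)[1, 1, 1]

    def test_boundary_is_strict(self):
        data = np.ones((2, 3, 3, 3), dtype=complex)
        data[:, 0, 0, 0] = 0.5  # exactly k * sigma for k=5, sigma=0.1
        noise = np.zeros((3, 3, 3), dtype=bool)
        noise[-1, -1, -1] = True
        data[:, -1, -1, -1] = [0.1, -0.1]  # sd 0.1 per channel population
        series = ComplexImageSeries(
            data=data, spacing=(1e-3,) * 3, seq=SequenceConstants(frame_interval=1.0)
        )
        sigma = np.concatenate(
            [data[:, -1, -1, -1].real, data[:, -1, -1, -1].imag]
        ).std()
        mask = fm.snr_mask(series, noise, k=0.5 / sigma)
        assert not mask[0, 0, 0]  # exactly at threshold -> excluded
        assert mask[1, 1, 1]

    def test_empty_or_degenerate_noise_region_rejected(self):
        series, support = self._series()
        with pytest.raises(ValueError, match="nonempty"):
            fm.snr_mask(series, np.zeros_like(support), k=5.0)


def _const_temps(delta_c, n_frames, frame_interval_s, baseline=20.0, shape=(2, 2, 2)):
    delta = np.full((n_frames,) + shape, float(delta_c))
    return TemperatureSeries(
        delta=delta, baseline_temperature=baseline, mask=None,
        spacing=(1e-3,) * 3, frame_interval=frame_interval_s,
    )


class TestCem43:
    @pytest.mark.parametrize(
        "temp_c,minutes,expected",
        [(43.0, 4.0, 4.0), (44.0, 1.0, 2.0), (42.0, 1.0, 0.25)],
    )
    def test_constant_temperature_arithmetic(self, temp_c, minutes, expected):
        n = int(minutes * 4)
        temps = _const_temps(temp_c - 20.0, n, 15.0)
        dose = fm.cem43(temps)
        assert dose.cem43[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_one_degree_rise_doubles_supra43_dose(self):
        a = fm.cem43(_const_temps(25.0, 4, 30.0)).cem43  # 45 degC
        b = fm.cem43(_const_temps(26.0, 4, 30.0)).cem43  # 46 degC
        assert np.allclose(b, 2 * a)

    def test_masked_voxels_accumulate_zero_dose(self):
        delta = np.full((3, 2, 2, 2), 25.0)
        mask = np.ones((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = False
        temps = TemperatureSeries(delta, 20.0, mask, (1e-3,) * 3, 60.0)
        dose = fm.cem43(temps)
        assert dose.cem43[0, 0, 0] == 0.0
        assert dose.cem43[1, 1, 1] > 0

    def test_nan_in_unmasked_voxel_rejected(self):
        delta = np.full((2, 2, 2, 2), 5.0)
        delta[1, 0, 0, 0] = np.nan
        temps = TemperatureSeries(delta, 20.0, None, (1e-3,) * 3, 60.0)
        with pytest.raises(ValueError, match="non-finite"):
            fm.cem43(temps)

    @given(
        deltas=hnp.arrays(
            float, (5, 3, 3, 3),
            elements=st.floats(min_value=-5.0, max_value=40.0),
        )
    )
    def test_appending_frames_never_decreases_dose(self, deltas):
        short = TemperatureSeries(deltas[:3], 20.0, None, (1e-3,) * 3, 10.0)
        full = TemperatureSeries(deltas, 20.0, None, (1e-3,) * 3, 10.0)
        assert (fm.cem43(full).cem43 >= fm.cem43(short).cem43 - 1e-12).all()

    def test_dose_additive_over_sonications(self):
        a = fm.cem43(_const_temps(24.0, 4, 30.0))
        b = fm.cem43(_const_temps(23.0, 2, 30.0))
        total = fm.accumulate_dose(a, b)
        assert np.allclose(total.cem43, a.cem43 + b.cem43)


class TestTreatmentVolumes:
    def test_dose_volume_takes_largest_region_only(self):
        dose = np.zeros((10, 10, 10))
        dose[1:3, 1:6, 1:6] = 300.0  # 50 voxels
        dose[6:8, 6:9, 6:11] = 300.0  # 2*3*4 = 24 voxels (clipped to grid)
        dm = DoseMap(dose, (3e-3, 1e-3, 1e-3))
        _, vol = fm.dose_volume(dm)
        assert vol == pytest.approx(50 * 3e-9 * 1e6)  # 0.15 cm^3

    def test_dose_threshold_is_inclusive(self):
        dose = np.zeros((3, 3, 3))
        dose[1, 1, 1] = 240.0
        _, vol = fm.dose_volume(DoseMap(dose, (1e-3,) * 3))
        assert vol == pytest.approx(1e-9 * 1e6)

    def test_hot_volume_counts_disjoint_blobs_dose_volume_does_not(self):
        delta = np.zeros((1, 12, 12, 12))
        delta[0, 1:3, 1:3, 1:3] = 30.0  # 8 voxels
        delta[0, 8:10, 8:10, 8:11] = 30.0  # 12 voxels
        temps = TemperatureSeries(delta, 20.0, None, (1e-3,) * 3, 240.0)
        hot = fm.hot_volume(temps, delta_threshold=10.0)
        assert hot == pytest.approx(20 * 1e-9 * 1e6)
        _, dose_vol = fm.dose_volume(fm.cem43(temps))
        assert dose_vol == pytest.approx(12 * 1e-9 * 1e6)

    def test_hot_volume_threshold_is_strict(self):
        delta = np.full((1, 2, 2, 2), 10.0)
        temps = TemperatureSeries(delta, 20.0, None, (1e-3,) * 3, 60.0)
        assert fm.hot_volume(temps, delta_threshold=10.0) == 0.0

    def test_gaussian_hot_volume_matches_half_maximum_sphere(self):
        sigma = 2e-3
        n = 40  # even grid: sphere centre between voxels (unbiased voxelization)
        ax = (np.arange(n) - (n - 1) / 2) * 0.5e-3
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        delta = 20.0 * np.exp(-(z**2 + y**2 + x**2) / (2 * sigma**2))
        temps = TemperatureSeries(delta[None], 20.0, None, (0.5e-3,) * 3, 2.16)
        truth = 4 / 3 * np.pi * (sigma * np.sqrt(2 * np.log(2))) ** 3 * 1e6
        assert abs(fm.hot_volume(temps) - truth) / truth < 0.05

    def test_masked_voxels_never_contribute(self):
        delta = np.full((1, 3, 3, 3), 30.0)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0] = True
        temps = TemperatureSeries(delta, 20.0, mask, (1e-3,) * 3, 600.0)
        assert fm.hot_volume(temps) == pytest.approx(9 * 1e-9 * 1e6)
        _, vol = fm.dose_volume(fm.cem43(temps))
        assert vol == pytest.approx(9 * 1e-9 * 1e6)
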