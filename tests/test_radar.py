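"""Radar chain unit tests: geometry, Range-FFT, MTI, fusion, filters."""

import dataclasses

import numpy as np
import pytest

from emowave import (AdcCube, BinSelection, ChestMotionModel, RadarConfig,
                     RangeTimeMatrix, SceneModel, extract_vital_sign,
                     fuse_phase, mti_mean_cancellation, phase_to_displacement,
                     range_fft, range_resolution, select_bins,
                     simulate_adc_cube, unwrap_phase)
from emowave.radar import C_LIGHT
from emowave.validation import dominant_frequency


class TestGeometry:
    def test_study_range_resolution(self, table2_config):
        assert round(range_resolution(table2_config), 4) == 0.0451

    def test_slope_times_ramp_is_bandwidth(self, table2_config):
        mhz = table2_config.slope * table2_config.ramp_end_time / 1e6
        assert round(mhz, 2) == 3790.97

    def test_resolution_halves_when_samples_double(self, table2_config):
        doubled = dataclasses.replace(table2_config, adc_samples=512)
        assert range_resolution(doubled) == pytest.approx(
            range_resolution(table2_config) / 2)

    def test_unit_resolution_when_sampled_bandwidth_is_half_c(self):
        cfg = RadarConfig(start_frequency=60e9, bandwidth=1.5e8,
                          slope=1.5e12, adc_sample_rate=1e6, adc_samples=100,
                          ramp_end_time=1e-4)
        assert range_resolution(cfg) == pytest.approx(1.0)

    def test_inconsistent_slope_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RadarConfig(slope=60e12)

    def test_wavelength_and_channels(self, table2_config):
        assert table2_config.wavelength == pytest.approx(5e-3)
        assert table2_config.n_virtual_channels == 12


class TestRangeFFT:
    def test_matches_naive_dft(self, small_config, rng):
        n = small_config.adc_samples
        n_chirps = 8
        cube = AdcCube(rng.standard_normal((2, n, n_chirps))
                       + 1j * rng.standard_normal((2, n, n_chirps)))
        rtms = range_fft(cube, small_config)
        dft = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        for ch in range(2):
            naive = dft @ cube.data[ch]
            err = np.abs(rtms[ch].values - naive).max() / np.abs(naive).max()
            assert err < 1e-9

    def test_zero_cube_gives_zero_rtm(self, small_config):
        cube = AdcCube(np.zeros((2, small_config.adc_samples, 4), complex))
        assert not np.any(range_fft(cube, small_config)[0].values)

    def test_static_target_peak_bin(self, small_config):
        r0 = 0.7
        scene = SceneModel(target=None, clutter=((r0, 1.0),), noise_sd=0.0)
        cube = simulate_adc_cube(small_config, scene, 1.0)
        rtm = range_fft(cube, small_config)[0]
        expected = round(r0 / rtm.range_bin_size)
        assert np.abs(rtm.values).mean(axis=1).argmax() == expected

    def test_two_separated_reflectors_give_two_peaks(self, small_config):
        dr = range_resolution(small_config)
        r1, r2 = 10 * dr, 20 * dr
        scene = SceneModel(target=None, clutter=((r1, 1.0), (r2, 0.8)),
                           noise_sd=0.0)
        cube = simulate_adc_cube(small_config, scene, 1.0)
        amp = np.abs(range_fft(cube, small_config)[0].values).mean(axis=1)
        local_max = [i for i in range(1, amp.size - 1)
                     if amp[i] > amp[i - 1] and amp[i] > amp[i + 1]
                     and amp[i] > 0.1 * amp.max()]
        assert {10, 20} <= set(local_max)

    def test_linearity(self, small_config, rng):
        shape = (2, small_config.adc_samples, 6)
        a = AdcCube(rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        b = AdcCube(rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        both = AdcCube(a.data + b.data)
        lhs = range_fft(both, small_config)[0].values
        rhs = (range_fft(a, small_config)[0].values
               + range_fft(b, small_config)[0].values)
        assert np.abs(lhs - rhs).max() < 1e-9 * np.abs(lhs).max()

    def test_dimension_mismatch_rejected(self, small_config):
        cube = AdcCube(np.zeros((2, 32, 4), complex))
        with pytest.raises(ValueError, match="fast-time"):
            range_fft(cube, small_config)


class TestMTI:
    def _rtm(self, values):
        return RangeTimeMatrix(np.asarray(values, complex), 0.045, 20.0)

    def test_rows_become_zero_mean(self, rng):
        rtm = self._rtm(rng.standard_normal((16, 50))
                        + 1j * rng.standard_normal((16, 50)))
        out = mti_mean_cancellation(rtm)
        scale = np.abs(rtm.values).max()
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12 * scale

    def test_static_scene_cancelled(self, small_config):
        scene = SceneModel(target=None, clutter=((0.5, 1.0),), noise_sd=0.0)
        cube = simulate_adc_cube(small_config, scene, 1.0)
        rtm = range_fft(cube, small_config)[0]
        out = mti_mean_cancellation(rtm)
        assert np.abs(out.values).max() < 1e-9 * np.abs(rtm.values).max()

    def test_variance_preserved(self, rng):
        rtm = self._rtm(rng.standard_normal((8, 100))
                        + 1j * rng.standard_normal((8, 100)))
        out = mti_mean_cancellation(rtm)
        before = rtm.values.var(axis=1)
        after = out.values.var(axis=1)
        assert np.allclose(before, after, rtol=1e-12)

    def test_single_chirp_rejected(self):
        with pytest.raises(ValueError, match="2 chirps"):
            mti_mean_cancellation(self._rtm(np.ones((4, 1))))


class TestBinSelection:
    def test_example_weights(self):
        values = np.zeros((40, 10), complex)
        amps = {10: 2.0, 11: 1.0, 12: 1.0, 13: 1.0, 14: 1.0}
        for b, a in amps.items():
            values[b] = a
        rtm = RangeTimeMatrix(values, 0.045, 20.0)
        sel = select_bins(rtm, k=5, search_window=(0.3, 1.5))
        assert sel.bin_indices[0] == 10
        np.testing.assert_allclose(
            sorted(sel.weights, reverse=True),
            [1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_weights_sum_to_one_and_nonnegative(self, rng):
        values = rng.standard_normal((64, 20)) + 1j * rng.standard_normal((64, 20))
        rtm = RangeTimeMatrix(values, 0.045, 20.0)
        sel = select_bins(rtm, k=5)
        assert sel.weights.sum() == pytest.approx(1.0)
        assert np.all(sel.weights >= 0)

    def test_simulated_target_bins_cluster(self, small_config):
        scene = SceneModel(target=ChestMotionModel(), noise_sd=0.05, seed=1)
        cube = simulate_adc_cube(small_config, scene, 10.0)
        rtm = mti_mean_cancellation(range_fft(cube, small_config)[0])
        sel = select_bins(rtm, k=5, search_window=(0.3, 1.5))
        target_bin = round(0.7 / rtm.range_bin_size)
        assert np.all(np.abs(sel.bin_indices - target_bin) <= 2)

    def test_window_without_enough_bins_rejected(self):
        rtm = RangeTimeMatrix(np.ones((8, 4), complex), 0.045, 20.0)
        with pytest.raises(ValueError, match="need at least"):
            select_bins(rtm, k=5, search_window=(10.0, 11.0))


class TestPhase:
    def test_unwrap_single_wrap_event(self):
        out = unwrap_phase(np.array([3.0, -3.0]))
        np.testing.assert_allclose(out, [3.0, 3.0 + (2 * np.pi - 6.0)])
        assert round(out[1], 5) == 3.28319

    def test_unwrap_smooth_series_unchanged(self):
        x = np.linspace(0, 3, 50)
        np.testing.assert_array_equal(unwrap_phase(x), x)

    def test_unwrap_linear_ramp(self):
        lam = 5e-3
        t = np.arange(2000) / 100.0
        truth = 4 * np.pi * (0.7 + 0.01 * t) / lam
        wrapped = np.angle(np.exp(1j * truth))
        recovered = unwrap_phase(wrapped)
        offset = truth[0] - recovered[0]
        assert np.abs(recovered + offset - truth).max() < 1e-9

    def test_fuse_single_bin_identity(self, rng):
        values = rng.standard_normal((8, 30)) + 1j * rng.standard_normal((8, 30))
        rtm = RangeTimeMatrix(values, 0.045, 20.0)
        sel = BinSelection(np.array([3]), np.array([1.0]), np.array([1.0]))
        expected = unwrap_phase(np.angle(values[3]))
        np.testing.assert_allclose(fuse_phase(rtm, sel), expected)

    def test_fuse_identical_phases_ignores_weights(self):
        phase = np.linspace(0, 2, 40)
        values = np.vstack([2.0 * np.exp(1j * phase),
                            0.5 * np.exp(1j * phase)])
        rtm = RangeTimeMatrix(values, 0.045, 20.0)
        sel = BinSelection(np.array([0, 1]), np.array([2.0, 0.5]),
                           np.array([0.8, 0.2]))
        np.testing.assert_allclose(fuse_phase(rtm, sel), phase, atol=1e-12)

    def test_fuse_drops_zero_magnitude_bin(self):
        phase = np.linspace(0, 1, 20)
        values = np.vstack([np.exp(1j * phase),
                            np.zeros(20, complex)])
        rtm = RangeTimeMatrix(values, 0.045, 20.0)
        sel = BinSelection(np.array([0, 1]), np.array([1.0, 1.0]),
                           np.array([0.5, 0.5]))
        np.testing.assert_allclose(fuse_phase(rtm, sel), phase, atol=1e-12)

    def test_noiseless_phase_fidelity(self, small_config):
        motion = ChestMotionModel()
        scene = SceneModel(target=motion, noise_sd=0.0)
        cube = simulate_adc_cube(small_config, scene, 10.0)
        rtm = range_fft(cube, small_config)[0]
        fused = fuse_phase(rtm, select_bins(rtm))
        t = np.arange(cube.n_chirps) / small_config.slow_time_rate
        truth = 4 * np.pi * motion.range_at(t) / small_config.wavelength
        resid = fused - truth
        assert np.abs(resid - resid.mean()).max() < 1e-6

    @pytest.mark.parametrize("delta,expected", [
        (4 * np.pi, 5e-3), (0.0, 0.0), (2.515, 1.0007e-3)])
    def test_phase_to_displacement(self, table2_config, delta, expected):
        assert phase_to_displacement(delta, table2_config) == pytest.approx(
            expected, abs=1e-6)


class TestExtraction:
    def test_recovers_both_rates(self, table2_config):
        scene = SceneModel(target=ChestMotionModel(resp_rate=0.25,
                                                   heart_rate=1.2),
                           clutter=((1.3, 0.8),), noise_sd=0.1, seed=5)
        cube = simulate_adc_cube(table2_config, scene, 60.0)
        bundle = extract_vital_sign(cube, table2_config)
        resp = dominant_frequency(bundle.respiration, 100.0, (0.1, 0.5))
        heart = dominant_frequency(bundle.heartbeat, 100.0, (0.8, 2.0))
        assert abs(resp - 0.25) <= 1 / 60.0
        assert abs(heart - 1.2) <= 1 / 60.0
        assert bundle.vital_sign.size == cube.n_chirps - 1
        assert bundle.respiration.size == bundle.vital_sign.size

    def test_channel_averaging_idempotent(self, small_config):
        single = dataclasses.replace(small_config, n_tx=1, n_rx=1)
        scene = SceneModel(noise_sd=0.0)
        cube2 = simulate_adc_cube(small_config, scene, 12.0)
        cube1 = simulate_adc_cube(single, scene, 12.0)
        b2 = extract_vital_sign(cube2, small_config)
        b1 = extract_vital_sign(cube1, single)
        np.testing.assert_allclose(b2.fused_phase, b1.fused_phase, atol=1e-9)

    def test_pure_respiration_tone_leaks_little_into_heartbeat_band(self):
        # a vital sign that is a pure 0.25 Hz tone must be rejected by the
        # 1.0-1.8 Hz heartbeat filter's stop band
        from scipy.signal import sosfiltfilt

        from emowave.radar import (_bandpass_sos, HEARTBEAT_BAND,
                                   HEARTBEAT_FILTER_ORDER, RESPIRATION_BAND,
                                   RESPIRATION_FILTER_ORDER)
        fs = 100.0
        vital = np.sin(2 * np.pi * 0.25 * np.arange(3000) / fs)
        resp = sosfiltfilt(
            _bandpass_sos(RESPIRATION_FILTER_ORDER, RESPIRATION_BAND, fs), vital)
        heart = sosfiltfilt(
            _bandpass_sos(HEARTBEAT_FILTER_ORDER, HEARTBEAT_BAND, fs), vital)
        rms = lambda x: np.sqrt(np.mean(x ** 2))
        assert rms(heart) < 0.05 * rms(resp)


class TestSimulation:
    def test_static_scene_constant_slow_time(self, small_config):
        scene = SceneModel(target=None, clutter=((0.6, 1.0),), noise_sd=0.0)
        cube = simulate_adc_cube(small_config, scene, 1.0)
        first = cube.data[0, :, 0]
        assert np.abs(cube.data[0] - first[:, None]).max() < 1e-12

    def test_seed_determinism(self, small_config):
        scene = SceneModel(noise_sd=0.2, seed=42)
        a = simulate_adc_cube(small_config, scene, 2.0)
        b = simulate_adc_cube(small_config, scene, 2.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_heartbeat_phase_excursion(self, small_config):
        # 1 mm displacement amplitude at 60 GHz: peak-to-peak phase
        # excursion 2 * 4*pi*d / lambda = 8*pi/5 ~ 5.03 rad
        motion = ChestMotionModel(resp_amplitude=1e-12, heart_amplitude=1e-3,
                                  heart_rate=1.25)
        cube = simulate_adc_cube(small_config,
                                 SceneModel(target=motion, noise_sd=0.0), 10.0)
        rtm = range_fft(cube, small_config)[0]
        fused = fuse_phase(rtm, select_bins(rtm))
        assert np.ptp(fused) == pytest.approx(8 * np.pi / 5, abs=0.01)

    def test_aliased_reflector_rejected(self, small_config):
        far = ChestMotionModel(baseline_range=2000.0)
        with pytest.raises(ValueError, match="aliased"):
            simulate_adc_cube(small_config, SceneModel(target=far), 1.0)

    def test_invalid_motion_rejected(self):
        with pytest.raises(ValueError):
            ChestMotionModel(resp_rate=0.8)
        with pytest.raises(ValueError):
            ChestMotionModel(heart_rate=0.2)

    def test_ramp_artifact_shifts_range(self):
        with_event = ChestMotionModel(motion_artifacts=((5.0, 1.0, 0.01),))
        without = ChestMotionModel()
        t = np.array([0.0, 5.5, 10.0])
        diff = with_event.range_at(t) - without.range_at(t)
        np.testing.assert_allclose(diff, [0.0, 0.005, 0.01], atol=1e-12)
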