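"""DSP front-end: clutter suppression, DC removal, beamforming, DACM
demodulation, band-pass extraction, windowing and standardization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarbp.dsp import (ArrayGeometry, NoTargetError, PhaseSignal, beamform,
                         dacm_demodulate, extract_rpw, range_fft, recenter_iq,
                         remove_dc_offset, segment_windows, select_range_angle,
                         standardize, suppress_clutter)
from radarbp.synth import RadarConfig, make_chest_motion, simulate_radar_cube

rng = np.random.default_rng(1)


class TestClutterSuppression:
    def test_identical_chirps_map_to_zero(self):
        cube = np.tile(rng.standard_normal((1, 8, 4))
                       + 1j * rng.standard_normal((1, 8, 4)), (16, 1, 1))
        np.testing.assert_allclose(suppress_clutter(cube), 0.0, atol=1e-12)

    def test_idempotent(self):
        cube = rng.standard_normal((10, 8, 4)) + 1j * rng.standard_normal((10, 8, 4))
        once = suppress_clutter(cube)
        np.testing.assert_allclose(suppress_clutter(once), once, atol=1e-12)

    def test_slow_time_mean_is_zero(self):
        static = rng.standard_normal((1, 8, 4))
        varying = rng.standard_normal((10, 8, 4))
        out = suppress_clutter(static + varying)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)

    def test_chirp_invariant_offset_is_removed_exactly(self):
        cube = rng.standard_normal((10, 8, 4)) + 1j * rng.standard_normal((10, 8, 4))
        offset = rng.standard_normal((1, 8, 4)) * (3 + 2j)
        np.testing.assert_allclose(suppress_clutter(cube + offset),
                                   suppress_clutter(cube), atol=1e-12)

    def test_single_chirp_rejected(self):
        with pytest.raises(ValueError):
            suppress_clutter(np.zeros((1, 8, 4)))


class TestDCRemoval:
    def test_constant_input_maps_to_zero(self):
        x = np.full(50, 2.0 + 3.0j)
        np.testing.assert_allclose(remove_dc_offset(x, 10), 0.0, atol=1e-12)

    def test_full_window_equals_global_mean_subtraction(self):
        x = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        np.testing.assert_allclose(remove_dc_offset(x, 64), x - x.mean(),
                                   atol=1e-12)

    def test_fast_sinusoid_passes_through(self):
        # period 10 samples << window 200 -> moving average barely attenuates
        t = np.arange(2000)
        x = np.exp(2j * np.pi * t / 10)
        out = remove_dc_offset(x, 200)
        mid = slice(200, -200)
        assert np.max(np.abs(out[mid] - x[mid])) < 0.05

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            remove_dc_offset(np.zeros(10), 0)
        with pytest.raises(ValueError):
            remove_dc_offset(np.zeros(10), 11)


class TestBeamforming:
    def setup_method(self):
        self.geom = ArrayGeometry(wavelength=0.004)

    def _steering(self, theta):
        # a plane wave from theta imposes exactly the weight phases on the
        # array, so the conjugate-weighted sum adds coherently
        return self.geom.weights(theta)

    def test_unit_modulus_weights(self):
        for theta in np.deg2rad([-40, -10, 0, 25]):
            np.testing.assert_allclose(np.abs(self.geom.weights(theta)), 1.0)

    def test_theta_zero_is_plain_sum(self):
        x = rng.standard_normal((20, 4)) + 1j * rng.standard_normal((20, 4))
        np.testing.assert_allclose(beamform(x, self.geom, 0.0), x.sum(axis=1))

    def test_coherent_gain_is_four(self):
        theta = np.deg2rad(17.0)
        sig = np.ones((5, 1)) * self._steering(theta)[None, :]
        np.testing.assert_allclose(np.abs(beamform(sig, self.geom, theta)), 4.0)

    def test_null_angle_rejects_source(self):
        # 4-element half-wavelength array: nulls where psi = pi*sin(theta)
        # steps by pi/2 -> steering to theta_null with source at theta0
        theta0 = 0.0
        theta_null = np.arcsin(0.5)      # array factor zero for 4 elements
        sig = np.ones((5, 1)) * self._steering(theta0)[None, :]
        assert np.max(np.abs(beamform(sig, self.geom, theta_null))) <= 0.05

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            beamform(np.zeros((5, 3), dtype=complex), self.geom, 0.0)


class TestDACM:
    def test_constant_iq_gives_zero_phase(self):
        ps = dacm_demodulate(np.full(50, 0.7), np.full(50, -0.2))
        np.testing.assert_allclose(ps.phi, 0.0, atol=1e-12)

    def test_constant_step_closed_form(self):
        # unit-circle rotation by 0.1 rad/sample: increment reduces to sin(0.1)
        k = np.arange(500)
        ps = dacm_demodulate(np.cos(0.1 * k), np.sin(0.1 * k))
        np.testing.assert_allclose(ps.phi, k * np.sin(0.1), atol=1e-9)

    def test_matches_unwrapped_arctangent_across_wraps(self):
        # steady drift crossing +-pi repeatedly; step sizes small enough
        # that the per-step discretization error (O(dphi^3)) stays < 1e-3
        # accumulated, yet the wrapped arctangent jumps many times
        local = np.random.default_rng(7)
        steps = 0.008 + local.uniform(-0.002, 0.002, 3000)
        phi_true = np.concatenate([[0.0], np.cumsum(steps)])
        assert phi_true[-1] > 4 * np.pi  # several wrap crossings
        ps = dacm_demodulate(np.cos(phi_true), np.sin(phi_true))
        assert np.max(np.abs(ps.phi - phi_true)) <= 1e-3
        assert np.max(np.abs(np.diff(ps.phi))) < 0.02  # continuous, no jumps

    def test_zero_magnitude_sample_rejected(self):
        i = np.array([1.0, 0.0, 1.0])
        q = np.array([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="invalid I/Q"):
            dacm_demodulate(i, q)


class TestExtractRPW:
    def test_heart_tone_amplitude_preserved(self):
        t = np.arange(4000) / 200.0
        phase = PhaseSignal(phi=np.sin(2 * np.pi * 1.2 * t), fs=200.0)
        out = extract_rpw(phase, band=(0.8, 10.0), out_fs=100.0)
        mid = out[len(out) // 4: -len(out) // 4]
        assert abs(mid.max() - 1.0) < 0.02

    def test_respiration_tone_attenuated_20db(self):
        t = np.arange(8000) / 200.0
        phase = PhaseSignal(phi=np.sin(2 * np.pi * 0.25 * t), fs=200.0)
        out = extract_rpw(phase, band=(0.8, 10.0), out_fs=100.0)
        mid = out[len(out) // 4: -len(out) // 4]
        assert np.max(np.abs(mid)) < 0.1  # >= 20 dB down

    def test_zero_in_zero_out(self):
        out = extract_rpw(PhaseSignal(phi=np.zeros(1000), fs=200.0))
        np.testing.assert_array_equal(out, np.zeros(500))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            extract_rpw(PhaseSignal(phi=np.zeros(100), fs=100.0), band=(0.8, 60.0))


class TestSegmentation:
    def test_window_counts(self):
        series = np.arange(3000.0)
        wins = segment_windows(series, 1000, overlap=0.5)
        assert len(wins) == 5
        assert all(len(w.x) == 1000 for w in wins)

    def test_no_overlap_tiles(self):
        wins = segment_windows(np.arange(3000.0), 1000, overlap=0.0)
        assert len(wins) == 3
        np.testing.assert_array_equal(wins[1].x, np.arange(1000.0) + 1000)

    def test_short_series_yields_empty_list(self):
        assert segment_windows(np.arange(10.0), 100) == []


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        x = standardize(rng.standard_normal(500) * 7 + 3)
        assert abs(x.mean()) < 1e-6
        assert abs(x.std() - 1) < 1e-3

    def test_constant_window_maps_to_zeros(self):
        np.testing.assert_array_equal(standardize(np.full(100, 4.2)), np.zeros(100))

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(standardize(a * x + b), standardize(x),
                                   atol=1e-6)


class TestRangeAngleSelection:
    def _cube(self, theta_deg, noise=0.02, seed=3):
        cfg = RadarConfig(n_chirps=1200)
        motion = make_chest_motion(duration=6.0, cardiac_amp=2e-4, resp_amp=1.5e-3)
        cube = simulate_radar_cube(motion, cfg, clutter_amp=0.5,
                                   dc_offset=0.1 + 0.05j, rng_seed=seed,
                                   target_angle=np.deg2rad(theta_deg),
                                   noise_sd=noise)
        return cube, cfg

    def test_recovers_known_bin_and_angle(self):
        cube, cfg = self._cube(theta_deg=15.0)
        geom = ArrayGeometry(wavelength=cfg.wavelength)
        b, theta = select_range_angle(cube, geom, fs=cfg.slow_rate)
        assert b == 6  # R0 = 0.5625 m on the 0.09375 m range grid
        assert theta == pytest.approx(np.deg2rad(15.0))

    def test_noiseless_recovery(self):
        cube, cfg = self._cube(theta_deg=-10.0, noise=0.0)
        geom = ArrayGeometry(wavelength=cfg.wavelength)
        b, theta = select_range_angle(cube, geom, fs=cfg.slow_rate)
        assert b == 6
        assert theta == pytest.approx(np.deg2rad(-10.0))

    def test_all_zero_cube_signals_no_target(self):
        geom = ArrayGeometry()
        with pytest.raises(NoTargetError):
            select_range_angle(np.zeros((100, 16, 4), dtype=complex), geom)


def test_recenter_iq_restores_circle_center():
    phi = np.linspace(0, 3.0, 400)
    z = np.exp(1j * phi) + (0.4 - 0.2j)
    out = recenter_iq(z)
    np.testing.assert_allclose(np.abs(out), 1.0, atol=1e-6)


def test_range_fft_localizes_static_target():
    cfg = RadarConfig(n_chirps=8)
    motion = make_chest_motion(duration=8 / 200, cardiac_amp=0.0, resp_amp=0.0)
    cube = simulate_radar_cube(motion, cfg)
    spectrum = np.abs(range_fft(cube)[0, :, 0])
    assert np.argmax(spectrum[:32]) == 6
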