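"""Preprocessing: decomposition, window statistics, 161-feature contract."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from fedhar.preprocessing import (
    DecompositionError,
    FeatureError,
    FeatureScaler,
    ScalerStateError,
    SynchronizationError,
    build_feature_manifest,
    cross_sensor_features,
    decompose_gravity_movement,
    extract_feature_vector,
    feature_manifest,
    gravity_statistics,
    movement_statistics,
    synchronize,
    zero_phase_response,
)
from fedhar.types import SensorStream


class TestSynchronize:
    def test_streams_on_common_grid_pass_through(self, rng):
        channels = rng.normal(0, 1, (3, 200))
        labels = np.array(["walk"] * 200)
        s1 = SensorStream("a", 50.0, channels, labels)
        s2 = SensorStream("a", 50.0, channels * 2, labels)
        merged = synchronize([s1, s2])
        assert merged.n_channels == 6
        np.testing.assert_allclose(merged.channels[:3], channels, atol=1e-12)
        np.testing.assert_allclose(merged.channels[3:], channels * 2, atol=1e-12)

    def test_ramp_resampled_from_25_to_50_hz_stays_on_the_line(self):
        t25 = np.arange(100) / 25.0
        ramp = 3.0 * t25 + 1.0
        s = SensorStream("a", 25.0, np.tile(ramp, (3, 1)), np.array(["x"] * 100))
        merged = synchronize([s], rate=50.0)
        t50 = merged.start_time + np.arange(merged.n_samples) / 50.0
        np.testing.assert_allclose(merged.channels[0], 3.0 * t50 + 1.0, atol=1e-10)

    def test_disjoint_intervals_raise(self):
        labels = np.array(["x"] * 100)
        s1 = SensorStream("a", 50.0, np.zeros((3, 100)), labels, start_time=0.0)
        s2 = SensorStream("a", 50.0, np.zeros((3, 100)), labels, start_time=100.0)
        with pytest.raises(SynchronizationError):
            synchronize([s1, s2])


class TestDecomposition:
    def test_constant_channel_is_pure_gravity(self):
        dec = decompose_gravity_movement(np.full(500, 0.81), 50.0)
        np.testing.assert_allclose(dec.gravity, 0.81, atol=1e-6)
        np.testing.assert_allclose(dec.movement, 0.0, atol=1e-6)

    def test_gravity_plus_movement_reconstructs_input(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 300)
            dec = decompose_gravity_movement(x, 50.0)
            np.testing.assert_allclose(dec.gravity + dec.movement, x, atol=1e-10)

    def test_5hz_sinusoid_barely_leaks_into_gravity(self):
        t = np.arange(5000) / 50.0
        x = np.sin(2 * np.pi * 5.0 * t)
        dec = decompose_gravity_movement(x, 50.0)
        core = dec.gravity[500:-500]  # ignore filter edge transients
        assert np.abs(core).max() <= 0.01

    def test_zero_phase_attenuation_matches_analytic_response(self):
        """Measured gain of the gravity path at 0.1 / 1 / 5 Hz agrees with
        the squared digital Butterworth magnitude within 5% relative."""
        fs = 50.0
        t = np.arange(int(200 * fs)) / fs
        for f in (0.1, 1.0, 5.0):
            x = np.sin(2 * np.pi * f * t)
            gravity = decompose_gravity_movement(x, fs).gravity
            core = slice(len(t) // 4, -len(t) // 4)
            measured = np.sqrt(2.0) * np.sqrt(np.mean(gravity[core] ** 2))
            expected = zero_phase_response(f, fs)[0]
            assert measured == pytest.approx(expected, rel=0.05)

    def test_half_power_at_cutoff(self):
        # forward-backward filtering squares the |H(fc)|^2 = 1/2 response
        assert zero_phase_response(1.0, 50.0)[0] == pytest.approx(0.5, rel=1e-6)

    def test_short_series_raises(self):
        with pytest.raises(DecompositionError):
            decompose_gravity_movement(np.zeros(5), 50.0)


class TestGravityStatistics:
    def test_constant_window(self):
        s = gravity_statistics(np.full(40, 2.5))
        assert s["mean"] == s["median"] == s["min"] == s["max"] == 2.5
        assert s["sd"] == 0.0 and s["cv"] == 0.0

    def test_hand_computed_values(self):
        s = gravity_statistics([1.0, 2.0, 3.0, 4.0])
        assert s["mean"] == pytest.approx(2.5)
        assert s["median"] == pytest.approx(2.5)
        assert s["sd"] == pytest.approx(np.sqrt(1.25))  # population sd
        assert s["cv"] == pytest.approx(np.sqrt(1.25) / 2.5)
        assert s["p25"] == pytest.approx(1.75)  # linear-interpolation quantile
        assert s["p75"] == pytest.approx(3.25)
        assert (s["min"], s["max"]) == (1.0, 4.0)

    def test_order_statistics_are_ordered(self, rng):
        for _ in range(50):
            s = gravity_statistics(rng.normal(0, 1, rng.integers(5, 100)))
            assert s["min"] <= s["p25"] <= s["median"] <= s["p75"] <= s["max"]

    def test_agrees_with_numpy_oracles(self, rng):
        for _ in range(100):
            x = rng.normal(0, 2, 64)
            s = gravity_statistics(x)
            assert s["mean"] == pytest.approx(np.mean(x), abs=1e-9)
            assert s["sd"] == pytest.approx(np.std(x), abs=1e-9)
            assert s["p25"] == pytest.approx(np.percentile(x, 25), abs=1e-9)


class TestMovementStatistics:
    def test_zero_window_convention(self):
        s = movement_statistics(np.zeros(64), 50.0)
        for key in ("energy", "specmag_mean", "specmag_sd", "dom_freq",
                    "dom_mag", "spec_centroid", "skew", "kurtosis"):
            assert s[key] == 0.0

    def test_symmetric_window_has_zero_skewness(self):
        x = np.concatenate([np.arange(1, 9), -np.arange(1, 9)])
        assert movement_statistics(x, 50.0)["skew"] == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_dominant_frequency_and_centroid(self):
        # 250 samples at 50 Hz puts 4 Hz exactly on DFT bin 20, so the
        # magnitude-weighted centroid is leakage-free
        t = np.arange(250) / 50.0
        s = movement_statistics(np.sin(2 * np.pi * 4.0 * t), 50.0)
        bin_width = 50.0 / 250
        assert abs(s["dom_freq"] - 4.0) <= bin_width
        assert abs(s["spec_centroid"] - 4.0) <= 0.5

    def test_off_bin_sinusoid_dominant_frequency_within_one_bin(self):
        t = np.arange(256) / 50.0
        s = movement_statistics(np.sin(2 * np.pi * 4.0 * t), 50.0)
        assert abs(s["dom_freq"] - 4.0) <= 50.0 / 256

    def test_agrees_with_scipy_oracles(self, rng):
        for _ in range(100):
            x = rng.normal(0, 1, 128)
            s = movement_statistics(x, 50.0)
            assert s["skew"] == pytest.approx(sp_stats.skew(x, bias=True), abs=1e-9)
            assert s["kurtosis"] == pytest.approx(
                sp_stats.kurtosis(x, fisher=False, bias=True), abs=1e-9
            )
            assert s["energy"] == pytest.approx(np.sum(x**2), abs=1e-9)

    def test_too_short_window_raises(self):
        with pytest.raises(FeatureError):
            movement_statistics(np.zeros(4), 50.0)


class TestCrossSensorFeatures:
    @staticmethod
    def _call(axes, mags, gravities):
        return cross_sensor_features(axes, mags, gravities)

    def test_duplicated_signal_correlates_perfectly(self, rng):
        base = rng.normal(0, 1, 200)
        axes = [base] * 6
        out = self._call(axes, [base, base], [np.zeros(200)] * 6)
        assert out["corr_s1_x_s1_y"] == pytest.approx(1.0)
        assert out["corr_s1_mag_s2_mag"] == pytest.approx(1.0)

    def test_independent_noise_is_nearly_uncorrelated(self, rng):
        n = 4000  # sampling fluctuation ~3/sqrt(n) ~ 0.05, well below 0.1
        series = [rng.normal(0, 1, n) for _ in range(8)]
        out = self._call(series[:6], series[6:], [np.zeros(n)] * 6)
        corrs = [v for k, v in out.items() if k.startswith("corr_")]
        assert len(corrs) == 28
        assert all(abs(c) < 0.1 for c in corrs)

    def test_constant_series_correlation_is_zero(self, rng):
        const = np.ones(100)
        noise = rng.normal(0, 1, 100)
        out = self._call([const] + [noise] * 5, [noise, noise], [const] * 6)
        assert out["corr_s1_x_s1_y"] == 0.0

    def test_cross_sensor_gravity_means(self):
        n = 50
        g1 = [np.ones(n), np.zeros(n), np.zeros(n)]
        g2 = [np.zeros(n), np.ones(n), np.zeros(n)]
        out = self._call([np.zeros(n)] * 6, [np.zeros(n)] * 2, g1 + g2)
        assert out["grav_cross_mean_x"] == pytest.approx(0.5)
        assert out["grav_cross_mean_y"] == pytest.approx(0.5)
        assert out["grav_cross_mean_z"] == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(FeatureError):
            self._call([np.zeros(10)] * 6, [np.zeros(9)] * 2, [np.zeros(10)] * 6)


class TestFeatureVector:
    def test_exactly_161_named_features(self, feature_pool):
        vec = extract_feature_vector(feature_pool[0])
        assert vec.values.shape == (161,)
        assert len(vec.manifest) == 161
        assert len(set(vec.manifest)) == 161

    def test_manifest_file_matches_code(self):
        assert feature_manifest() == build_feature_manifest()

    def test_extraction_is_deterministic(self, feature_pool):
        a = extract_feature_vector(feature_pool[3])
        b = extract_feature_vector(feature_pool[3])
        assert np.array_equal(a.values, b.values)

    def test_finite_for_random_windows(self, rng):
        for _ in range(10):
            window = rng.normal(0, 1, (250, 6))
            vec = extract_feature_vector(window)
            assert np.all(np.isfinite(vec.values))

    def test_wrong_channel_count_raises(self, rng):
        with pytest.raises(FeatureError):
            extract_feature_vector(rng.normal(0, 1, (250, 4)))


class TestFeatureScaler:
    def test_affine_map_by_hand(self):
        scaler = FeatureScaler().fit(np.array([[0.0], [10.0]]))
        assert scaler.transform(np.array([5.0]))[0] == pytest.approx(0.5)

    def test_constant_feature_maps_to_zero(self):
        scaler = FeatureScaler().fit(np.array([[3.0], [3.0]]))
        assert scaler.transform(np.array([3.0]))[0] == 0.0
        assert scaler.transform(np.array([99.0]))[0] == 0.0

    def test_out_of_range_values_clip(self):
        scaler = FeatureScaler().fit(np.array([[0.0], [10.0]]))
        assert scaler.transform(np.array([12.0]))[0] == 1.0
        assert scaler.transform(np.array([-2.0]))[0] == 0.0

    def test_training_values_scale_into_unit_interval(self, rng):
        mat = rng.normal(0, 5, (40, 7))
        scaled = FeatureScaler().fit(mat).transform(mat)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_scaling_idempotent_on_scaled_data(self, rng):
        mat = rng.normal(0, 5, (40, 7))
        scaled = FeatureScaler().fit(mat).transform(mat)
        again = FeatureScaler().fit(scaled).transform(scaled)
        np.testing.assert_allclose(again, scaled, atol=1e-12)

    def test_unfitted_scaler_raises(self):
        with pytest.raises(ScalerStateError):
            FeatureScaler().transform(np.zeros(3))

    def test_json_round_trip(self, rng):
        mat = rng.normal(0, 1, (10, 161))
        scaler = FeatureScaler().fit(mat)
        clone = FeatureScaler.from_json(scaler.to_json())
        np.testing.assert_allclose(clone.transform(mat), scaler.transform(mat))
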