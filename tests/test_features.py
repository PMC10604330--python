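import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from posturekit import (
    GaitParameters,
    Label,
    apply_normalizer,
    build_feature_matrix,
    channel_correlations,
    differentiate,
    fit_normalizer,
    resample,
    synthesize_session,
)
from posturekit.features import FEATURE_NAMES, FeatureMatrix
from posturekit.protocol import ProtocolScript


def _const_session(n=1500, rate=100.0):
    p = ProtocolScript(timeline=((Label.STANDING, n / rate),))
    return synthesize_session(p, GaitParameters(noise_sd=0.0, seed=0), rate)


class TestDifferentiate:
    def test_constant_track_has_zero_derivatives(self):
        vel, acc = differentiate(np.full((100, 4), 3.0), 100.0)
        assert np.all(vel == 0.0)
        assert np.all(acc == 0.0)

    def test_linear_ramp_interior_velocity_exact(self):
        t = np.arange(200) / 100.0
        angles = np.tile(10.0 * t, (4, 1)).T
        vel, _ = differentiate(angles, 100.0)
        np.testing.assert_allclose(vel[1:-1], 10.0, rtol=1e-12)

    def test_sine_velocity_amplitude_within_truncation_bound(self):
        rate, f, A = 100.0, 1.0, 30.0
        t = np.arange(1000) / rate
        angles = (A * np.sin(2 * np.pi * f * t))[:, None]
        vel, _ = differentiate(angles, rate)
        expected = 2 * np.pi * f * A
        # central differences: relative truncation error (2*pi*f/rate)^2 / 6
        bound = expected * (2 * np.pi * f / rate) ** 2 / 6 * 1.5
        assert abs(vel[1:-1].max() - expected) <= bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            differentiate(np.zeros((2, 4)), 100.0)

    def test_integration_recovers_angles(self):
        p = ProtocolScript(timeline=((Label.WALKING, 20.0),))
        s = synthesize_session(p, GaitParameters(noise_sd=0.0, seed=0), 100.0)
        vel, _ = differentiate(s.angles, s.rate)
        rebuilt = s.angles[0] + cumulative_trapezoid(vel, dx=1 / s.rate, axis=0, initial=0.0)
        np.testing.assert_allclose(rebuilt[5:-5], s.angles[5:-5], atol=0.2)


class TestFeatureMatrix:
    def test_shape_and_rate(self, one_cycle_session):
        fm = build_feature_matrix(one_cycle_session)
        assert fm.values.shape == (one_cycle_session.n_samples, 12)
        assert fm.rate == one_cycle_session.rate

    def test_constant_pose_zeroes_derivative_columns(self):
        fm = build_feature_matrix(_const_session())
        derivative_cols = [i for i, name in enumerate(FEATURE_NAMES) if not name.endswith("angle")]
        assert len(derivative_cols) == 8
        assert np.all(fm.values[:, derivative_cols] == 0.0)

    def test_column_order_is_joint_major(self):
        assert FEATURE_NAMES[6] == "knee_angle"
        assert FEATURE_NAMES[:3] == ("pelvis_angle", "pelvis_vel", "pelvis_acc")

    def test_nonfinite_rejected(self):
        vals = np.zeros((10, 12))
        vals[3, 4] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            FeatureMatrix(values=vals, rate=100.0)


class TestResample:
    def test_decimation_counts(self, one_cycle_session):
        out = resample(one_cycle_session, 25.0)
        assert out.n_samples == one_cycle_session.n_samples // 4
        assert out.rate == 25.0

    def test_identity_rate(self, one_cycle_session):
        assert resample(one_cycle_session, one_cycle_session.rate) is one_cycle_session

    def test_non_divisor_rejected(self, one_cycle_session):
        with pytest.raises(ValueError, match="divide"):
            resample(one_cycle_session, 30.0)

    def test_label_runs_match_brute_force_decimation(self, one_cycle_session):
        k = 4
        out = resample(one_cycle_session, 25.0)
        brute = np.array([one_cycle_session.labels[i] for i in range(0, one_cycle_session.n_samples, k)])
        assert np.array_equal(out.labels, brute)
        # a 50-sample run at 100 Hz survives as 12 or 13 samples at 25 Hz
        stw = int(np.sum(out.labels == Label.STW))
        assert stw in (12, 13)


class TestNormalization:
    def test_self_normalization_is_zscore(self, one_cycle_session):
        fm = build_feature_matrix(one_cycle_session)
        stats = fit_normalizer(fm)
        out = apply_normalizer(fm, stats)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_guard(self):
        fm = build_feature_matrix(_const_session())
        stats = fit_normalizer(fm)
        out = apply_normalizer(fm, stats)
        assert np.all(np.isfinite(out.values))
        derivative_cols = [i for i, n in enumerate(FEATURE_NAMES) if not n.endswith("angle")]
        assert np.all(out.values[:, derivative_cols] == 0.0)

    def test_normalization_invertible(self, one_cycle_session):
        fm = build_feature_matrix(one_cycle_session)
        stats = fit_normalizer(fm)
        back = stats.invert(stats.apply(fm.values))
        np.testing.assert_allclose(back, fm.values, rtol=1e-12, atol=1e-9)

    def test_cross_subject_stats_differ(self, one_cycle_session):
        fm = build_feature_matrix(one_cycle_session)
        stats = fit_normalizer(fm)
        other = synthesize_session(
            ProtocolScript(timeline=((Label.SITTING, 20.0),)), GaitParameters(seed=3), 100.0
        )
        out = apply_normalizer(build_feature_matrix(other), stats)
        assert np.abs(out.values.mean(axis=0)).max() > 0.5


class TestChannelCorrelations:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        vals = np.tile(x[:, None], (1, 12))
        vals[:, 1] = -x
        corr = channel_correlations(FeatureMatrix(values=vals, rate=100.0))
        assert np.all(np.diag(corr.matrix) == 1.0)
        assert corr.matrix[0, 1] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(12345)
        vals = rng.normal(size=(10_000, 12))
        corr = channel_correlations(FeatureMatrix(values=vals, rate=100.0))
        off = corr.matrix[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_zero_variance_column_flagged_not_propagated(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(500, 12))
        vals[:, 3] = 2.5
        corr = channel_correlations(FeatureMatrix(values=vals, rate=100.0))
        assert corr.undefined == (3,)
        assert np.isnan(corr.matrix[3, 0]) and np.isnan(corr.matrix[0, 3])
        assert corr.matrix[3, 3] == 1.0
        assert np.isfinite(corr.matrix[0, 1])
        # flagged pairs never appear in the threshold report
        assert all("_" in a and "_" in b for a, b, _ in corr.pairs_above(0.0) if True)

    def test_correlated_session_channels_exceed_threshold(self, one_cycle_session):
        corr = channel_correlations(build_feature_matrix(one_cycle_session))
        pairs = corr.pairs_above(0.3)
        names = {(a, b) for a, b, _ in pairs}
        assert ("hip_angle", "knee_angle") in names  # both driven by sitting


def test_correlation_frame_labels(one_cycle_session):
    corr = channel_correlations(build_feature_matrix(one_cycle_session))
    df = corr.to_frame()
    assert list(df.columns) == list(FEATURE_NAMES)
    assert df.shape == (12, 12)
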