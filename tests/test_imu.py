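"""Attitude extraction: calibration, tilt formulas, smoothing, fusion, steering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartbrush import errors, imu
from smartbrush.imu import SteeringLabel

from conftest import make_stream


class TestCalibration:
    def test_constant_gyro_bias_recovered(self):
        s = make_stream(np.arange(100) / 50.0, [0, 0, 1], gyro=[0.5, -0.2, 0.1])
        cal = imu.calibrate_rest(s, rest_window=2.0)
        np.testing.assert_allclose(cal.gyro_bias, [0.5, -0.2, 0.1], atol=1e-12)

    def test_pure_gravity_gives_zero_accel_bias(self):
        s = make_stream(np.arange(100) / 50.0, [0, 0, 1])
        cal = imu.calibrate_rest(s, rest_window=2.0)
        np.testing.assert_allclose(cal.accel_bias, [0, 0, 0], atol=1e-12)

    def test_accel_bias_after_gravity_removal(self):
        s = make_stream(np.arange(100) / 50.0, [0.02, -0.01, 1.0])
        cal = imu.calibrate_rest(s, rest_window=2.0)
        np.testing.assert_allclose(cal.accel_bias, [0.02, -0.01, 0.0], atol=1e-6)
        # applying the calibration zeroes the biases on the rest segment
        calibrated = imu.apply_calibration(s, cal)
        np.testing.assert_allclose(
            np.linalg.norm(calibrated[imu.ACCEL_COLUMNS].mean()), 1.0, atol=1e-9
        )

    def test_motion_in_rest_window_raises_naming_threshold(self):
        s = make_stream(np.arange(100) / 50.0, [0, 0, 1], gyro=[80.0, 0, 0])
        with pytest.raises(errors.CalibrationError, match="5.0 deg/s"):
            imu.calibrate_rest(s, rest_window=2.0, gyro_threshold=5.0)


class TestTiltFormulas:
    @pytest.mark.parametrize(
        "ay,expected", [(0.0, 0.0), (1.0, 90.0), (0.7071, 45.0), (-1.0, -90.0)]
    )
    def test_pitch_examples(self, ay, expected):
        assert imu.pitch_from_accel(ay) == pytest.approx(expected, abs=0.01)

    def test_pitch_out_of_range(self):
        with pytest.raises(errors.OutOfRangeError):
            imu.pitch_from_accel(1.2)

    @pytest.mark.parametrize(
        "ax,pitch,expected",
        [(0.0, 0.0, 0.0), (-0.7071, 0.0, 45.0), (0.5, 60.0, -90.0)],
    )
    def test_roll_examples(self, ax, pitch, expected):
        assert imu.roll_from_accel(ax, pitch) == pytest.approx(expected, abs=0.01)

    def test_roll_gimbal_degeneracy(self):
        with pytest.raises(errors.GimbalLockError):
            imu.roll_from_accel(0.1, 89.999)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pitch=st.floats(-80.0, 80.0),
        roll=st.floats(-85.0, 85.0),
    )
    def test_roundtrip_arcsine_domain(self, pitch, roll):
        """Gravity from (pitch, roll) feeds back through the tilt formulas."""
        g = imu.gravity_from_attitude(pitch, roll)
        p = imu.pitch_from_accel(g[1])
        r = imu.roll_from_accel(g[0], p)
        assert p == pytest.approx(pitch, abs=1e-6)
        assert r == pytest.approx(roll, abs=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pitch=st.floats(-80.0, 80.0),
        roll=st.floats(-179.0, 179.0),
    )
    def test_roundtrip_full_roll_range(self, pitch, roll):
        """atan2 recovery extends the roll round trip past +/-90 degrees."""
        g = imu.gravity_from_attitude(pitch, roll)
        p, r = imu.attitude_from_accel(*g)
        assert p == pytest.approx(pitch, abs=1e-6)
        assert r == pytest.approx(roll, abs=1e-6)

    def test_attitude_undefined_for_zero_accel(self):
        with pytest.raises(errors.UndefinedAttitudeError):
            imu.attitude_from_accel(0.0, 0.0, 0.0)


class TestKalmanSmoothing:
    def test_constant_stream_unchanged(self, static_stream):
        out = imu.smooth_stream(static_stream)
        pd.testing.assert_frame_equal(out, static_stream)

    def test_noise_variance_reduced(self, rng):
        t = np.arange(500) / 50.0
        noisy = make_stream(t, [0, 0, 1])
        noisy["ax"] += rng.normal(0, 0.05, len(t))
        out = imu.smooth_stream(noisy)
        assert out["ax"].var() < noisy["ax"].var()

    def test_step_response_monotone_no_overshoot(self):
        t = np.arange(100) / 50.0
        s = make_stream(t, [0, 0, 1])
        s.loc[50:, "ax"] = 1.0
        out = imu.smooth_stream(s)["ax"].to_numpy()
        assert np.all(np.diff(out[49:]) >= -1e-12)
        assert out.max() <= 1.0 + 1e-12

    def test_preserves_length_and_timestamps(self, rng):
        t = np.arange(77) / 50.0
        s = make_stream(t, [0, 0, 1])
        out = imu.smooth_stream(s)
        assert len(out) == len(s)
        np.testing.assert_array_equal(out["t"], s["t"])

    def test_non_monotone_time_rejected(self, static_stream):
        bad = static_stream.copy()
        bad.loc[3, "t"] = bad.loc[2, "t"]
        with pytest.raises(errors.StreamOrderError):
            imu.smooth_stream(bad)


class TestFusion:
    def test_static_reference_pose(self, static_stream):
        att = imu.fuse_orientation(static_stream)
        np.testing.assert_allclose(att["pitch"], 0.0, atol=1e-9)
        np.testing.assert_allclose(att["roll"], 0.0, atol=1e-9)

    def test_static_30deg_pitch(self):
        s = make_stream(np.arange(50) / 50.0, [0.0, 0.5, 0.8660])
        att = imu.fuse_orientation(s)
        np.testing.assert_allclose(att["pitch"], 30.0, atol=0.5)

    def test_pitch_ramp_tracked(self):
        """Rotating gravity through a 0->40 degree pitch ramp is tracked <1 deg RMS."""
        from smartbrush.imu import _euler_rate_matrix, gravity_from_attitude

        fs, dur = 50.0, 4.0
        t = np.arange(int(fs * dur)) / fs
        pitch = 40.0 * t / dur
        accel = np.array([gravity_from_attitude(p, 0.0) for p in pitch])
        gyro = np.zeros((len(t), 3))
        for i in range(1, len(t)):
            rate = np.array([(pitch[i] - pitch[i - 1]) * fs, 0.0, 0.0])
            gyro[i] = _euler_rate_matrix(np.radians(pitch[i - 1]), 0.0) @ rate
        s = make_stream(t, [0, 0, 1])
        s[imu.ACCEL_COLUMNS] = accel
        s[imu.GYRO_COLUMNS] = gyro
        att = imu.fuse_orientation(s)
        rms = np.sqrt(np.mean((att["pitch"].to_numpy() - pitch) ** 2))
        assert rms < 1.0

    def test_zero_accel_rejected(self, static_stream):
        bad = static_stream.copy()
        bad.loc[10, imu.ACCEL_COLUMNS] = 0.0
        with pytest.raises(errors.UndefinedAttitudeError):
            imu.fuse_orientation(bad)


class TestSteering:
    @pytest.mark.parametrize(
        "pitch,roll,az,ax,expected",
        [
            (0.0, 100.0, 0.9, 0.0, SteeringLabel.FACE_UP),
            (0.0, 160.0, -0.85, 0.0, SteeringLabel.FACE_DOWN),
            (100.0, 60.0, 0.0, 0.0, SteeringLabel.FACE_RIGHT),
            (0.0, 0.0, 0.0, 0.0, SteeringLabel.FACE_UP),  # roll band
            (0.0, 170.0, 0.0, 0.0, SteeringLabel.FACE_DOWN),
            (-100.0, 60.0, 0.0, 0.0, SteeringLabel.FACE_LEFT),
            (0.0, 60.0, 0.0, 0.9, SteeringLabel.FACE_LEFT),
            (0.0, 60.0, 0.0, -0.9, SteeringLabel.FACE_RIGHT),
            (0.0, 60.0, 0.0, 0.0, SteeringLabel.UNKNOWN),
        ],
    )
    def test_rule_table(self, pitch, roll, az, ax, expected):
        assert imu.classify_steering(pitch, roll, az, ax) is expected

    def test_precedence_up_wins_over_right(self):
        # az > 0.8 (UP) co-occurring with a RIGHT pitch band: UP fires first
        assert imu.classify_steering(60.0, 100.0, 0.9, 0.0) is SteeringLabel.FACE_UP

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        pitch=st.floats(-180.0, 180.0),
        roll=st.floats(-180.0, 180.0),
        az=st.floats(-1.0, 1.0),
        ax=st.floats(-1.0, 1.0),
    )
    def test_total_and_deterministic(self, pitch, roll, az, ax):
        a = imu.classify_steering(pitch, roll, az, ax)
        b = imu.classify_steering(pitch, roll, az, ax)
        assert a is b and isinstance(a, SteeringLabel)


class TestFeatures:
    def _frames(self, n=3):
        return pd.DataFrame(
            {
                "t": np.arange(n) / 50.0,
                "pitch": np.zeros(n),
                "roll": np.ones(n),
                "yaw": np.full(n, 2.0),
            }
        )

    def test_default_dimension(self):
        X = imu.extract_features(self._frames())
        assert X.shape == (3, 3)

    def test_extended_dimension(self):
        frames = self._frames()
        stream = make_stream(frames["t"], [0, 0, 1])
        X = imu.extract_features(frames, stream, feature_set="extended")
        assert X.shape == (3, 6)

    def test_misaligned_lengths_rejected(self):
        frames = self._frames(3)
        stream = make_stream(np.arange(4) / 50.0, [0, 0, 1])
        with pytest.raises(errors.AlignmentError):
            imu.extract_features(frames, stream, feature_set="extended")
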