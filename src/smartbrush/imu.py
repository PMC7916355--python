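"""Attitude features from raw nine-axis toothbrush IMU streams.

The toothbrush carries a 9-axis IMU (accelerometer in g, gyroscope in
deg/s, magnetometer in µT) in the carrier (body) frame; the fixed frame is
North-East-Down (NED).  At rest the accelerometer measures the gravity
direction, from which the elevation (pitch) and roll angles follow:

    pitch = asin(ay)                 (normalized accel, degrees)
    roll  = -asin(ax / cos(pitch))

The arcsine roll formula has principal range [-90, 90] degrees; the
full-range recovery used by the fusion path is

    roll = atan2(-ax, az)  in (-180, 180].

A rule table on (az, ax, roll, pitch) classifies the brush steering into
face-up / face-down / face-left / face-right, applied with fixed precedence
UP, DOWN, LEFT, RIGHT (first match wins; no match -> UNKNOWN).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CalibrationError,
    GimbalLockError,
    OutOfRangeError,
    StreamOrderError,
    UndefinedAttitudeError,
)

SESSION_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
ACCEL_COLUMNS = ["ax", "ay", "az"]
GYRO_COLUMNS = ["gx", "gy", "gz"]
MAG_COLUMNS = ["mx", "my", "mz"]
ATTITUDE_COLUMNS = ["t", "pitch", "roll", "yaw"]

#: Gravity reference on the toothbrush holder (brush upright), in g.
HOLDER_GRAVITY = np.array([0.0, 0.0, 1.0])


class SteeringLabel(str, enum.Enum):
    FACE_UP = "FACE_UP"
    FACE_DOWN = "FACE_DOWN"
    FACE_LEFT = "FACE_LEFT"
    FACE_RIGHT = "FACE_RIGHT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class RestCalibration:
    """Holder ("rest") calibration: sensor biases and reference attitude.

    accel_bias is the mean rest accelerometer reading minus the holder
    gravity reference (0, 0, 1) g, so applying the calibration leaves a
    unit-magnitude gravity vector; gyro_bias is the mean rest rate.
    """

    accel_bias: np.ndarray
    gyro_bias: np.ndarray
    reference_orientation: tuple[float, float, float]


def _require_monotone_time(t: np.ndarray) -> None:
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise StreamOrderError("stream timestamps must be strictly increasing")


def wrap_angle(angle_deg):
    """Wrap angle(s) to the interval (-180, 180] degrees."""
    wrapped = np.asarray(-((-np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0))
    return wrapped if wrapped.ndim else float(wrapped)


def calibrate_rest(
    stream: pd.DataFrame,
    rest_window: float = 2.0,
    gyro_threshold: float = 5.0,
) -> RestCalibration:
    """Estimate sensor biases from the initial on-holder rest segment.

    Parameters
    ----------
    stream : DataFrame with the session columns (t, ax..az, gx..gz, mx..mz).
    rest_window : seconds of low-motion data required at the stream start.
    gyro_threshold : maximum gyro magnitude (deg/s) tolerated as "at rest".

    Raises
    ------
    CalibrationError
        If the first ``rest_window`` seconds contain motion above
        ``gyro_threshold`` deg/s.
    """
    t = stream["t"].to_numpy(dtype=float)
    _require_monotone_time(t)
    mask = t <= t[0] + rest_window
    if mask.sum() < 2:
        raise CalibrationError(
            f"fewer than 2 samples in the first {rest_window} s; cannot calibrate"
        )
    gyro = stream.loc[mask, GYRO_COLUMNS].to_numpy(dtype=float)
    gyro_mag = np.linalg.norm(gyro, axis=1)
    if np.any(gyro_mag > gyro_threshold):
        raise CalibrationError(
            "no qualifying rest segment: gyro magnitude "
            f"{gyro_mag.max():.2f} deg/s exceeds the motion threshold "
            f"{gyro_threshold} deg/s within the first {rest_window} s"
        )
    accel = stream.loc[mask, ACCEL_COLUMNS].to_numpy(dtype=float)
    accel_mean = accel.mean(axis=0)
    accel_bias = accel_mean - HOLDER_GRAVITY
    gyro_bias = gyro.mean(axis=0)
    ref = attitude_from_accel(*accel_mean)
    return RestCalibration(
        accel_bias=accel_bias,
        gyro_bias=gyro_bias,
        reference_orientation=(ref[0], ref[1], 0.0),
    )


def apply_calibration(stream: pd.DataFrame, calib: RestCalibration) -> pd.DataFrame:
    """Return a copy of the stream with accel/gyro biases subtracted."""
    out = stream.copy()
    out[ACCEL_COLUMNS] = out[ACCEL_COLUMNS].to_numpy(dtype=float) - calib.accel_bias
    out[GYRO_COLUMNS] = out[GYRO_COLUMNS].to_numpy(dtype=float) - calib.gyro_bias
    return out


def pitch_from_accel(ay: float, tol: float = 0.05) -> float:
    """Elevation angle (degrees) from the normalized y accelerometer axis."""
    if abs(ay) > 1.0 + tol:
        raise OutOfRangeError(
            f"|ay| = {abs(ay):.4f} exceeds 1 g beyond tolerance {tol}; "
            "accelerometer not normalized"
        )
    return float(np.degrees(np.arcsin(np.clip(ay, -1.0, 1.0))))


def roll_from_accel(ax: float, pitch: float, gimbal_margin: float = 0.1) -> float:
    """Roll angle (degrees) from the x accelerometer axis at known pitch.

    Principal-range formula -asin(ax / cos(pitch)); valid for |roll| <= 90.
    Raises GimbalLockError within ``gimbal_margin`` degrees of pitch +/-90,
    where the tilt normalization degenerates.
    """
    if abs(pitch) >= 90.0 - gimbal_margin:
        raise GimbalLockError(
            f"pitch {pitch:.2f} deg within {gimbal_margin} deg of gimbal lock; "
            "use the fused orientation instead"
        )
    ratio = ax / np.cos(np.radians(pitch))
    return float(-np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0))))


def attitude_from_accel(ax: float, ay: float, az: float):
    """Full-range (pitch, roll) in degrees from a gravity-direction reading.

    pitch = asin(ay_n) in [-90, 90]; roll = atan2(-ax_n, az_n) in (-180, 180],
    which extends the arcsine roll formula past +/-90 degrees using the sign
    of az.
    """
    vec = np.array([ax, ay, az], dtype=float)
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise UndefinedAttitudeError("all-zero accelerometer reading: attitude undefined")
    axn, ayn, azn = vec / norm
    pitch = float(np.degrees(np.arcsin(np.clip(ayn, -1.0, 1.0))))
    roll = float(np.degrees(np.arctan2(-axn, azn)))
    return pitch, wrap_angle(roll)


def gravity_from_attitude(pitch: float, roll: float) -> np.ndarray:
    """Body-frame gravity direction (g) for given pitch/roll in degrees.

    Inverse of :func:`attitude_from_accel`:
    (ax, ay, az) = (-sin(roll) cos(pitch), sin(pitch), cos(roll) cos(pitch)).
    """
    p, r = np.radians(pitch), np.radians(roll)
    return np.array(
        [-np.sin(r) * np.cos(p), np.sin(p), np.cos(r) * np.cos(p)]
    )


def smooth_stream(
    stream: pd.DataFrame,
    process_var: float = 0.5,
    measurement_var: float = 0.05,
) -> pd.DataFrame:
    """Per-axis scalar Kalman smoothing of the nine sensor channels.

    Constant-position (random-walk) state model per channel:
    x_k = x_{k-1} + w, z_k = x_k + v, with Var(w) = process_var and
    Var(v) = measurement_var.  The state is initialized at the first
    measurement, so a constant stream passes through unchanged.  Length and
    timestamps are preserved.

    The defaults keep the steady-state gain high (~0.92, about one frame of
    lag): brushing dynamics are fast (2 Hz strokes, >100 deg/s rates), so
    heavy smoothing would corrupt the gyro signal the orientation fusion
    integrates.  Lower ``process_var`` for slowly varying streams.
    """
    t = stream["t"].to_numpy(dtype=float)
    _require_monotone_time(t)
    out = stream.copy()
    channels = [c for c in SESSION_COLUMNS[1:] if c in stream.columns]
    z = stream[channels].to_numpy(dtype=float)
    x = np.empty_like(z)
    x[0] = z[0]
    state = z[0].copy()
    p = np.zeros(len(channels))
    for k in range(1, len(z)):
        p = p + process_var
        gain = p / (p + measurement_var)
        state = state + gain * (z[k] - state)
        p = (1.0 - gain) * p
        x[k] = state
    out[channels] = x
    return out


def _euler_rate_matrix(pitch_rad: float, roll_rad: float) -> np.ndarray:
    """Map (pitch_rate, roll_rate, yaw_rate) -> body angular velocity.

    For the rotation order R_nb = Ry(roll) Rx(pitch) Rz(yaw):
    omega = pitch_rate * Ry(roll) e_x + roll_rate * e_y
            + yaw_rate * Ry(roll) Rx(pitch) e_z.
    """
    cp, sp = np.cos(pitch_rad), np.sin(pitch_rad)
    cr, sr = np.cos(roll_rad), np.sin(roll_rad)
    return np.array(
        [
            [cr, 0.0, -sr * cp],
            [0.0, 1.0, sp],
            [sr, 0.0, cr * cp],
        ]
    )


def yaw_from_mag(mag: np.ndarray, pitch: float, roll: float) -> float:
    """Tilt-compensated magnetic heading (degrees) in (-180, 180]."""
    p, r = np.radians(pitch), np.radians(roll)
    ry = np.array(
        [[np.cos(-r), 0.0, -np.sin(-r)], [0.0, 1.0, 0.0], [np.sin(-r), 0.0, np.cos(-r)]]
    )
    rx = np.array(
        [[1.0, 0.0, 0.0], [0.0, np.cos(-p), np.sin(-p)], [0.0, -np.sin(-p), np.cos(-p)]]
    )
    m_level = rx @ (ry @ np.asarray(mag, dtype=float))
    return wrap_angle(float(np.degrees(np.arctan2(-m_level[1], m_level[0]))))


def fuse_orientation(stream: pd.DataFrame, alpha: float = 0.98) -> pd.DataFrame:
    """Complementary accel/mag + gyro fusion to Euler angles (NED).

    Per sample the gyro propagates the previous attitude through the Euler
    kinematic map, and the accelerometer (pitch, roll) and tilt-compensated
    magnetometer (yaw) correct it with weight ``1 - alpha``.  The filter is
    initialized from the first accel/mag sample, so a static stream
    reproduces the closed-form tilt angles exactly.

    Returns a DataFrame with columns t, pitch, roll, yaw (degrees).
    """
    t = stream["t"].to_numpy(dtype=float)
    _require_monotone_time(t)
    accel = stream[ACCEL_COLUMNS].to_numpy(dtype=float)
    gyro = stream[GYRO_COLUMNS].to_numpy(dtype=float)
    has_mag = all(c in stream.columns for c in MAG_COLUMNS)
    mag = stream[MAG_COLUMNS].to_numpy(dtype=float) if has_mag else None
    if np.any(np.linalg.norm(accel, axis=1) < 1e-9):
        raise UndefinedAttitudeError("all-zero accelerometer sample: attitude undefined")

    n = len(t)
    pitch = np.empty(n)
    roll = np.empty(n)
    yaw = np.empty(n)
    p0, r0 = attitude_from_accel(*accel[0])
    y0 = yaw_from_mag(mag[0], p0, r0) if has_mag and np.linalg.norm(mag[0]) > 1e-9 else 0.0
    pitch[0], roll[0], yaw[0] = p0, r0, y0
    for k in range(1, n):
        dt = t[k] - t[k - 1]
        m = _euler_rate_matrix(np.radians(pitch[k - 1]), np.radians(roll[k - 1]))
        if abs(np.linalg.det(m)) > 1e-6:
            rates = np.linalg.solve(m, gyro[k])  # deg/s in (pitch, roll, yaw)
        else:
            rates = np.zeros(3)  # gimbal degenerate: rely on the accel correction
        pred_p = pitch[k - 1] + rates[0] * dt
        pred_r = roll[k - 1] + rates[1] * dt
        pred_y = yaw[k - 1] + rates[2] * dt
        meas_p, meas_r = attitude_from_accel(*accel[k])
        pitch[k] = np.clip(pred_p + (1.0 - alpha) * (meas_p - pred_p), -90.0, 90.0)
        roll[k] = wrap_angle(pred_r + (1.0 - alpha) * wrap_angle(meas_r - pred_r))
        if has_mag and np.linalg.norm(mag[k]) > 1e-9:
            meas_y = yaw_from_mag(mag[k], pitch[k], roll[k])
            yaw[k] = wrap_angle(pred_y + (1.0 - alpha) * wrap_angle(meas_y - pred_y))
        else:
            yaw[k] = wrap_angle(pred_y)
    return pd.DataFrame({"t": t, "pitch": pitch, "roll": roll, "yaw": yaw})


def classify_steering(pitch: float, roll: float, az: float, ax: float) -> SteeringLabel:
    """Rule-based brush steering from attitude and calibrated accel.

    Fixed precedence (first match wins):
      FACE_UP    az >  0.8  or  -45 < roll < 45
      FACE_DOWN  az < -0.8  or  150 < roll < 180
      FACE_LEFT  ax >  0.8  or  -150 < pitch < -45
      FACE_RIGHT ax < -0.8  or   45 < pitch < 150
    No rule matching yields UNKNOWN.  Total and deterministic.
    """
    if az > 0.8 or -45.0 < roll < 45.0:
        return SteeringLabel.FACE_UP
    if az < -0.8 or 150.0 < roll < 180.0:
        return SteeringLabel.FACE_DOWN
    if ax > 0.8 or -150.0 < pitch < -45.0:
        return SteeringLabel.FACE_LEFT
    if ax < -0.8 or 45.0 < pitch < 150.0:
        return SteeringLabel.FACE_RIGHT
    return SteeringLabel.UNKNOWN


def steering_labels(frames: pd.DataFrame, stream: pd.DataFrame) -> list[SteeringLabel]:
    """Vectorized steering classification over aligned attitude + raw frames."""
    _check_alignment(frames, stream)
    return [
        classify_steering(p, r, az, ax)
        for p, r, az, ax in zip(
            frames["pitch"], frames["roll"], stream["az"], stream["ax"]
        )
    ]


def _check_alignment(frames: pd.DataFrame, stream: pd.DataFrame) -> None:
    if len(frames) != len(stream):
        raise AlignmentError(
            f"attitude frames ({len(frames)}) and stream ({len(stream)}) differ in length"
        )
    if not np.allclose(
        frames["t"].to_numpy(dtype=float), stream["t"].to_numpy(dtype=float), atol=1e-9
    ):
        raise AlignmentError("attitude frames and stream timestamps do not match")


def extract_features(
    frames: pd.DataFrame,
    stream: pd.DataFrame | None = None,
    feature_set: str = "attitude",
) -> np.ndarray:
    """Assemble the classifier feature matrix.

    feature_set "attitude" -> (pitch, roll, yaw); "extended" additionally
    appends the calibrated accelerometer axes (requires ``stream``).
    Standardization is owned by the classifier (fitted training statistics),
    not by this function.
    """
    base = frames[["pitch", "roll", "yaw"]].to_numpy(dtype=float)
    if feature_set == "attitude":
        return base
    if feature_set == "extended":
        if stream is None:
            raise AlignmentError("extended feature set requires the raw stream")
        _check_alignment(frames, stream)
        return np.hstack([base, stream[ACCEL_COLUMNS].to_numpy(dtype=float)])
    raise ValueError(f"unknown feature_set {feature_set!r}")
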