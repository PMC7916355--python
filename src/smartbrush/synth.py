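"""Synthetic labeled brushing sessions with the structure the method assumes.

Real brushing recordings of this kind are proprietary/confidential, so this
module emulates their statistical structure:
15 brushing regions, each with a characteristic mean toothbrush attitude
(pitch, roll, yaw), a 2 Hz sinusoidal stroke oscillation riding on pitch
(Bass strokes are short vertical sweeps), Gaussian attitude noise that may
be AR(1)-correlated, occasional single-frame spike disturbances (knocks
against teeth), and a per-user systematic attitude offset modeling grip
habits.  From the true attitude the raw nine-axis channels are synthesized
exactly through the same kinematic model the fusion inverts:

    accel = R(pitch, roll) (0,0,1) g + noise          (gravity direction)
    gyro  = M(pitch, roll) d(attitude)/dt + noise     (body rates, deg/s)
    mag   = R_nb(yaw, pitch, roll) B_ned + noise      (µT)

so a noise-free session round-trips through the feature extractor exactly.

The default region attitude table is a package constant constructed from
the qualitative Bass-technique postures (outer surfaces ~45-degree tilt
toward the gum line, inner surfaces steeper with the brush inside the
arch, chewing surfaces face-up/face-down), not measured data: upper/lower
jaws flip the roll sign, left/right/front arch positions spread the yaw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .imu import (
    SESSION_COLUMNS,
    _euler_rate_matrix,
    extract_features,
    fuse_orientation,
    gravity_from_attitude,
    smooth_stream,
    wrap_angle,
)

#: NED geomagnetic reference field, µT (horizontal 22, vertical 40: mid-latitude).
MAG_REFERENCE_NED = np.array([22.0, 0.0, 40.0])

DEFAULT_FS = 50.0
DEFAULT_NOISE_SIGMA = 5.0
DEFAULT_OFFSET_SIGMA = 5.0
DEFAULT_ACCEL_NOISE = 0.01  # g
DEFAULT_GYRO_NOISE = 1.0  # deg/s
DEFAULT_MAG_NOISE = 0.5  # µT


@dataclass(frozen=True)
class RegionProfile:
    region: int
    name: str
    pitch: float
    roll: float
    yaw: float
    stroke_amp: float = 10.0  # deg, on pitch
    stroke_freq: float = 2.0  # Hz
    noise_sigma: float = DEFAULT_NOISE_SIGMA  # deg, per attitude angle


_PROFILE_TABLE = [
    # region, name, pitch, roll, yaw
    (1, "outer incisors", 0.0, 40.0, 0.0),
    (2, "upper right outer", 10.0, 40.0, -70.0),
    (3, "lower right outer", -10.0, -40.0, -70.0),
    (4, "upper left outer", 10.0, 40.0, 70.0),
    (5, "lower left outer", -10.0, -40.0, 70.0),
    (6, "upper right flank", 20.0, 0.0, -110.0),
    (7, "upper incisor inner", 50.0, 20.0, 10.0),
    (8, "upper left flank", 20.0, 0.0, 110.0),
    (9, "lower right flank", -20.0, 150.0, -110.0),
    (10, "lower incisor inner", -50.0, -20.0, 10.0),
    (11, "lower left flank", -20.0, 150.0, 110.0),
    (12, "upper right inner", 30.0, 55.0, -135.0),
    (13, "lower right inner", -30.0, -55.0, -135.0),
    (14, "upper left inner", 30.0, 55.0, 135.0),
    (15, "lower left inner", -30.0, -55.0, 135.0),
]


def default_profiles(noise_sigma: float = DEFAULT_NOISE_SIGMA) -> list[RegionProfile]:
    """The 15 packaged region profiles (ids 1..15)."""
    return [
        RegionProfile(region=r, name=n, pitch=p, roll=rl, yaw=y, noise_sigma=noise_sigma)
        for r, n, p, rl, y in _PROFILE_TABLE
    ]


@dataclass
class SessionSpec:
    """Everything that determines one simulated session (seed-reproducible)."""

    user: str = "user1"
    user_offset: tuple = (0.0, 0.0, 0.0)  # deg systematic (pitch, roll, yaw)
    noise_multiplier: float = 1.0
    order: tuple = tuple(range(1, 16))  # region visit order
    dwell: float = 4.0  # seconds per region (scalar or per-region sequence)
    fs: float = DEFAULT_FS
    seed: int = 0
    noise_ar: float = 0.9  # AR(1) coefficient of the attitude noise (tremor band-limit)
    transition_seconds: float = 0.2  # continuous move between regions (label 0)
    spike_prob: float = 0.0  # per-frame probability of a 1-frame disturbance
    spike_scale: float = 45.0  # deg, disturbance magnitude scale (one angle)
    rest_seconds: float = 0.0  # on-holder rest prefix (label 0)
    stroke: bool = True


@dataclass
class BrushingSession:
    """A labeled simulated session: raw stream + ground truth."""

    frame: pd.DataFrame  # t, ax..az, gx..gz, mx..mz, label
    truth: pd.DataFrame  # t, pitch, roll, yaw (noise included, pre-sensor)
    user: str
    spec: SessionSpec
    _cached_xy: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def xy(self, source: str = "fused") -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and labels.

        source "fused": Kalman-smoothed stream through orientation fusion
        (the deployment pipeline); "truth": the generator's attitude.
        """
        if source == "fused":
            if self._cached_xy is None:
                att = fuse_orientation(smooth_stream(self.frame))
                self._cached_xy = (extract_features(att), self.labels)
            return self._cached_xy
        if source == "truth":
            return self.truth[["pitch", "roll", "yaw"]].to_numpy(dtype=float), self.labels
        raise ConfigError(f"unknown feature source {source!r}")


def _ar1_noise(rng, n: int, sigma: float, ar: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sigma."""
    white = rng.normal(0.0, 1.0, n)
    if ar <= 0.0:
        return sigma * white
    out = np.empty(n)
    out[0] = white[0]
    scale = np.sqrt(1.0 - ar**2)
    for i in range(1, n):
        out[i] = ar * out[i - 1] + scale * white[i]
    return sigma * out


def _rotation_nb(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """NED -> body rotation R_nb = Ry(roll) Rx(pitch) Rz(yaw), degrees in."""
    p, r, y = np.radians([pitch, roll, yaw])
    rx = np.array([[1, 0, 0], [0, np.cos(p), np.sin(p)], [0, -np.sin(p), np.cos(p)]])
    ry = np.array([[np.cos(r), 0, -np.sin(r)], [0, 1, 0], [np.sin(r), 0, np.cos(r)]])
    rz = np.array([[np.cos(y), np.sin(y), 0], [-np.sin(y), np.cos(y), 0], [0, 0, 1]])
    return ry @ rx @ rz


def simulate_session(
    spec: SessionSpec, profiles: list[RegionProfile] | None = None
) -> BrushingSession:
    """Generate one labeled session; fully determined by ``spec.seed``."""
    profiles = profiles if profiles is not None else default_profiles()
    by_id = {p.region: p for p in profiles}
    dwell = np.broadcast_to(np.asarray(spec.dwell, dtype=float), (len(spec.order),))
    if np.any(dwell <= 0):
        raise ConfigError(f"dwell times must be positive, got {spec.dwell}")
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.fs

    seg_angles, seg_labels = [], []
    n_rest = int(round(spec.rest_seconds * spec.fs))
    if n_rest:
        seg_angles.append(np.zeros((n_rest, 3)))
        seg_labels.append(np.zeros(n_rest, dtype=int))
    t_offset = n_rest * dt
    n_trans = int(round(spec.transition_seconds * spec.fs))
    prev_mean = np.zeros(3) if n_rest else None
    for region, dw in zip(spec.order, dwell):
        prof = by_id[region]
        n = int(round(dw * spec.fs))
        mean = np.array([prof.pitch, prof.roll, prof.yaw]) + np.asarray(
            spec.user_offset, dtype=float
        )
        if prev_mean is not None and n_trans:
            # Continuous hand movement between regions; ground truth is
            # neither region, so transition frames carry label 0.
            frac = np.linspace(0.0, 1.0, n_trans + 2)[1:-1, None]
            step = np.asarray(wrap_angle(mean - prev_mean))
            trans = prev_mean + frac * step
            sigma_t = prof.noise_sigma * spec.noise_multiplier
            if sigma_t > 0:
                for j in range(3):
                    trans[:, j] += _ar1_noise(rng, n_trans, sigma_t, spec.noise_ar)
            seg_angles.append(trans)
            seg_labels.append(np.zeros(n_trans, dtype=int))
            t_offset += n_trans * dt
        prev_mean = mean
        tt = t_offset + np.arange(n) * dt
        angles = np.tile(mean, (n, 1))
        if spec.stroke and prof.stroke_amp:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            angles[:, 0] += prof.stroke_amp * np.sin(
                2.0 * np.pi * prof.stroke_freq * tt + phase
            )
        sigma = prof.noise_sigma * spec.noise_multiplier
        if sigma > 0:
            for j in range(3):
                angles[:, j] += _ar1_noise(rng, n, sigma, spec.noise_ar)
        if spec.spike_prob > 0:
            # Single-frame knocks: one angle takes a transient excursion.
            hits = np.flatnonzero(rng.random(n) < spec.spike_prob)
            axes = rng.integers(0, 3, len(hits))
            angles[hits, axes] += rng.normal(0.0, spec.spike_scale, len(hits))
        seg_angles.append(angles)
        seg_labels.append(np.full(n, region, dtype=int))
        t_offset = tt[-1] + dt if n else t_offset

    angles = np.vstack(seg_angles)
    labels = np.concatenate(seg_labels)
    angles[:, 0] = np.clip(angles[:, 0], -89.0, 89.0)
    angles[:, 1] = wrap_angle(angles[:, 1])
    angles[:, 2] = wrap_angle(angles[:, 2])
    n_total = len(labels)
    t = np.arange(n_total) * dt

    accel = np.empty((n_total, 3))
    gyro = np.zeros((n_total, 3))
    mag = np.empty((n_total, 3))
    for i in range(n_total):
        p, r, y = angles[i]
        accel[i] = gravity_from_attitude(p, r)
        mag[i] = _rotation_nb(y, p, r) @ MAG_REFERENCE_NED
        if i:
            rates = wrap_angle(angles[i] - angles[i - 1]) / dt  # (pitch, roll, yaw) deg/s
            gyro[i] = _euler_rate_matrix(
                np.radians(angles[i - 1, 0]), np.radians(angles[i - 1, 1])
            ) @ rates
    if spec.noise_multiplier > 0:
        accel += rng.normal(0.0, DEFAULT_ACCEL_NOISE * spec.noise_multiplier, accel.shape)
        gyro += rng.normal(0.0, DEFAULT_GYRO_NOISE * spec.noise_multiplier, gyro.shape)
        mag += rng.normal(0.0, DEFAULT_MAG_NOISE * spec.noise_multiplier, mag.shape)

    frame = pd.DataFrame(
        np.column_stack([t, accel, gyro, mag]), columns=SESSION_COLUMNS
    )
    frame["label"] = labels
    truth = pd.DataFrame(
        {"t": t, "pitch": angles[:, 0], "roll": angles[:, 1], "yaw": angles[:, 2]}
    )
    return BrushingSession(frame=frame, truth=truth, user=spec.user, spec=spec)


@dataclass
class Benchmark:
    train: list
    val: list
    test: list
    manifest: dict


def make_benchmark(
    n_users: int = 5,
    train_per_region: int = 200,
    val_per_region: int = 50,
    test_per_region: int = 100,
    fs: float = DEFAULT_FS,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    offset_sigma: float = DEFAULT_OFFSET_SIGMA,
    noise_ar: float = 0.9,
    spike_prob: float = 0.0,
    seed: int = 0,
    full_scale: bool = False,
) -> Benchmark:
    """Multi-user train/val/test sessions emulating the study protocol.

    Desk scale by default (200 train / 50 val / 100 test frames per region
    per user); ``full_scale`` switches to 2000 train / 1000 test frames
    per region.  Every user gets one session per split, visiting
    the 15 regions in the prescribed order; train/val/test use disjoint
    seeds, so their noise draws are independent.
    """
    if full_scale:
        train_per_region, val_per_region, test_per_region = 2000, 500, 1000
    profiles = default_profiles(noise_sigma=noise_sigma)
    root = np.random.default_rng(seed)
    splits = {"train": train_per_region, "val": val_per_region, "test": test_per_region}
    sessions: dict[str, list] = {k: [] for k in splits}
    manifest: dict = {
        "seed": seed,
        "n_users": n_users,
        "fs": fs,
        "noise_sigma": noise_sigma,
        "offset_sigma": offset_sigma,
        "noise_ar": noise_ar,
        "spike_prob": spike_prob,
        "frames_per_region": splits,
        "sessions": [],
    }
    for u in range(n_users):
        offset = root.normal(0.0, offset_sigma, 3)
        for si, (split, per_region) in enumerate(splits.items()):
            spec = SessionSpec(
                user=f"user{u + 1}",
                user_offset=tuple(offset),
                order=tuple(range(1, 16)),
                dwell=per_region / fs,
                fs=fs,
                seed=int(root.integers(0, 2**31 - 1)),
                noise_ar=noise_ar,
                spike_prob=spike_prob,
            )
            sessions[split].append(simulate_session(spec, profiles))
            manifest["sessions"].append(
                {"user": spec.user, "split": split, "seed": spec.seed,
                 "frames": per_region * 15}
            )
    return Benchmark(
        train=sessions["train"],
        val=sessions["val"],
        test=sessions["test"],
        manifest=manifest,
    )
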