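import numpy as np
import pandas as pd
import pytest

from smartbrush.imu import SESSION_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stream(t, accel, gyro=None, mag=None):
    """Assemble a session DataFrame from per-sample arrays."""
    n = len(t)
    accel = np.broadcast_to(np.asarray(accel, dtype=float), (n, 3))
    gyro = np.broadcast_to(
        np.zeros(3) if gyro is None else np.asarray(gyro, dtype=float), (n, 3)
    )
    mag = np.broadcast_to(
        np.array([22.0, 0.0, 40.0]) if mag is None else np.asarray(mag, dtype=float),
        (n, 3),
    )
    return pd.DataFrame(
        np.column_stack([np.asarray(t, dtype=float), accel, gyro, mag]),
        columns=SESSION_COLUMNS,
    )


@pytest.fixture
def static_stream():
    """One second at 50 Hz on the holder: gravity along +z, no motion."""
    return make_stream(np.arange(50) / 50.0, [0.0, 0.0, 1.0])


def brute_force_posterior(x, patterns, labels, classes, sigma, priors):
    """Independent naive double-loop Gaussian kernel-sum PNN posterior."""
    scores = []
    for ci, c in enumerate(classes):
        total = 0.0
        count = 0
        for xj, lj in zip(patterns, labels):
            if lj == c:
                d2 = float(np.sum((np.asarray(x) - np.asarray(xj)) ** 2))
                total += np.exp(-d2 / (2.0 * sigma[ci] ** 2))
                count += 1
        scores.append(priors[ci] * total / count)
    scores = np.asarray(scores)
    return scores / scores.sum()
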