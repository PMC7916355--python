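"""Personalizing a generalized model to a target user (model migration).

A model trained on source users generalizes imperfectly because every user
holds and moves the brush slightly differently (systematic attitude
offsets).  The PNN stores patterns rather than iteratively trained
weights, so personalization reduces to: append the target user's labeled
calibration patterns (optionally capping the retained source patterns per
class), then re-tune (sigma scale, delta, K) on a held-out split of the
target's sessions.  Labels come from the calibration protocol — the user
brushes a scripted region sequence after watching the technique — so the
target data arrive implicitly labeled.
"""

from __future__ import annotations

import copy

import numpy as np

from .errors import MigrationError
from .pnn import PNNClassifier
from .pso import PsoConfig, _as_xy, apply_triple, optimize, session_accuracy, tune_rpnn
from .rpnn import RPNNClassifier


def _split_sessions(sessions, val_fraction: float, rng):
    """Held-out split for re-tuning; splits frames if only one session."""
    sessions = [(X, y) for X, y in (_as_xy(s) for s in sessions)]
    if len(sessions) >= 2:
        n_val = max(1, int(round(val_fraction * len(sessions))))
        order = rng.permutation(len(sessions))
        val_idx = set(order[:n_val].tolist())
        train = [s for i, s in enumerate(sessions) if i not in val_idx]
        val = [s for i, s in enumerate(sessions) if i in val_idx]
        return train, val
    X, y = sessions[0]
    cut = int(round((1.0 - val_fraction) * len(y)))
    cut = min(max(cut, 1), len(y) - 1)
    return [(X[:cut], y[:cut])], [(X[cut:], y[cut:])]


def _cap_source_patterns(pnn: PNNClassifier, cap: int, rng) -> PNNClassifier:
    """Seeded per-class subsample of the stored source patterns."""
    keep = []
    for ci in range(len(pnn.classes_)):
        idx = np.flatnonzero(pnn.pattern_labels_ == ci)
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep.append(idx)
    keep = np.concatenate(keep)
    out = copy.deepcopy(pnn)
    out.patterns_ = pnn.patterns_[keep]
    out.pattern_labels_ = pnn.pattern_labels_[keep]
    out._refresh_derived()
    return out


def migrate(
    source_model: RPNNClassifier,
    target_sessions,
    config: PsoConfig | None = None,
    source_cap: int | None = None,
    val_fraction: float = 0.25,
    seed: int = 0,
    user_id: str | None = None,
) -> RPNNClassifier:
    """Personalize ``source_model`` for the user behind ``target_sessions``.

    Pure function: the source model is never mutated.  With no target data
    the source model is returned (as a tagged copy) unchanged.  With
    ``source_cap=0`` the personalized model is fit from the target data
    alone.  ``config=None`` or ``config.n_iters=0`` skips the re-tuning
    stage (patterns are still appended).

    Raises
    ------
    MigrationError
        If any target session lacks labels — run the scripted calibration
        protocol (prescribed region sequence) to obtain labeled data.
    """
    target_sessions = list(target_sessions)
    if not target_sessions:
        out = copy.deepcopy(source_model)
        out.user_id = user_id
        return out
    pairs = [_as_xy(s) for s in target_sessions]
    for X, y in pairs:
        if y is None or len(y) == 0 or np.all(np.asarray(y) == 0):
            raise MigrationError(
                "target sessions are unlabeled; collect calibration data with the "
                "scripted brushing sequence (prescribed region order) to label them"
            )
    rng = np.random.default_rng(seed)
    X_t = np.vstack([X[y != 0] for X, y in pairs])
    y_t = np.concatenate([y[y != 0] for _, y in pairs])

    if source_cap == 0:
        # Degenerate cap: discard the source entirely, fit on target alone.
        params = source_model.pnn_.get_params()
        pnn = PNNClassifier(**params).fit(X_t, y_t)
    else:
        base = source_model.pnn_
        if source_cap is not None:
            base = _cap_source_patterns(base, source_cap, rng)
        pnn = base.add_patterns(X_t, y_t)

    personalized = copy.copy(source_model)
    personalized.pnn_ = pnn
    personalized.classes_ = pnn.classes_
    personalized.user_id = user_id

    if config is not None and config.n_iters > 0 and config.n_particles >= 2:
        tune_train, tune_val = _split_sessions(target_sessions, val_fraction, rng)
        personalized, _ = tune_rpnn(
            tune_train, tune_val, config=config, fitted=personalized
        )
        personalized.user_id = user_id
    return personalized
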