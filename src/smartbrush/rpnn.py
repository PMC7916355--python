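"""Recurrent memory unit over PNN posteriors for streaming region decisions.

Each class keeps an accumulator P_update that integrates its (gain-scaled)
posterior over time.  At step t with raw posterior P(t):

    P*_i(t) = K * P_i(t)          if t != 0, else 0
    winner (argmax_i P_i(t), lowest index on ties):
        P_update,i(t) = (1 - delta) * (P_update,i(t-1) + P*_i(t))
    all other classes:
        P_update,i(t) = delta * (P_update,i(t-1) + P*_i(t))

delta in [0, 1) is the forgetting factor (small delta suppresses
non-winning classes quickly); K > 0 is the memory-length gain.  The emitted
label is the argmax of the accumulator, so isolated frames whose raw
posterior flips to another class are outvoted by accumulated evidence.
While the accumulator is identically zero (stream start) the raw posterior
argmax is emitted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .errors import DimensionError, InputContractError
from .pnn import PNNClassifier


@dataclass
class MemoryState:
    """Per-class accumulator vector and step counter of the memory unit."""

    p_update: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n_classes: int) -> "MemoryState":
        return cls(p_update=np.zeros(n_classes), t=0)


def memory_update(
    state: MemoryState, p: np.ndarray, delta: float, k: float
) -> MemoryState:
    """One step of the recurrent memory recursion (pure function).

    ``p`` must be a probability vector matching the state dimension.  The
    winner is keyed on the *raw* posterior maximum (lowest index on ties);
    exactly one component takes the (1 - delta) branch.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != state.p_update.shape:
        raise DimensionError(
            f"posterior has {p.shape} but memory state has {state.p_update.shape}"
        )
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise InputContractError(
            f"p is not a probability vector (sum={p.sum():.6f}, min={p.min():.3g})"
        )
    p_star = k * p if state.t != 0 else np.zeros_like(p)
    winner = int(np.argmax(p))
    combined = state.p_update + p_star
    new = delta * combined
    new[winner] = (1.0 - delta) * combined[winner]
    return MemoryState(p_update=new, t=state.t + 1)


def reset(state: MemoryState) -> MemoryState:
    """Fresh all-zero state of the same dimension."""
    return MemoryState.zeros(len(state.p_update))


class RPNNClassifier(ClassifierMixin, BaseEstimator):
    """PNN wrapped with the recurrent per-class memory unit.

    ``predict`` treats its input as one temporally ordered session: the
    memory state is reset at the start of every call, so back-to-back calls
    on separate sessions are independent.

    Parameters
    ----------
    pnn : PNNClassifier or None
        Base classifier (cloned at fit; default construction if None).
    delta : float in [0, 1)
        Forgetting factor of the memory unit.
    k : float > 0
        Memory-length gain applied to the current posterior.
    normalize_state : bool
        If True, reported accumulator snapshots are sum-normalized (the
        decision itself always uses the raw accumulator).
    """

    def __init__(
        self,
        pnn: PNNClassifier | None = None,
        delta: float = 0.2,
        k: float = 1.0,
        normalize_state: bool = False,
    ):
        self.pnn = pnn
        self.delta = delta
        self.k = k
        self.normalize_state = normalize_state

    def _check_hyper(self):
        if not (0.0 <= self.delta < 1.0):
            raise InputContractError(f"delta must be in [0, 1), got {self.delta}")
        if not self.k > 0:
            raise InputContractError(f"k must be positive, got {self.k}")

    def fit(self, X, y):
        self._check_hyper()
        base = self.pnn if self.pnn is not None else PNNClassifier()
        self.pnn_ = clone(base).fit(X, y)
        self.classes_ = self.pnn_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Raw per-frame PNN posteriors (memory not applied)."""
        check_is_fitted(self, "pnn_")
        return self.pnn_.predict_proba(X)

    def decision_path_(self, X):
        """Labels plus accumulator snapshots for one ordered session."""
        check_is_fitted(self, "pnn_")
        self._check_hyper()
        proba = self.pnn_.predict_proba(X)
        state = MemoryState.zeros(len(self.classes_))
        labels = np.empty(len(proba), dtype=self.classes_.dtype)
        snapshots = np.empty_like(proba)
        for i, p in enumerate(proba):
            state = memory_update(state, p, self.delta, self.k)
            if np.all(state.p_update == 0.0):
                labels[i] = self.classes_[int(np.argmax(p))]
            else:
                labels[i] = self.classes_[int(np.argmax(state.p_update))]
            snap = state.p_update
            if self.normalize_state and snap.sum() > 0:
                snap = snap / snap.sum()
            snapshots[i] = snap
        return labels, snapshots

    def predict(self, X) -> np.ndarray:
        """Temporally smoothed labels for one ordered session."""
        return self.decision_path_(X)[0]


def classify_stream(model: RPNNClassifier, features) -> list[tuple]:
    """Per-step (region label, accumulator snapshot) for a feature sequence."""
    features = np.asarray(features, dtype=float)
    if len(features) == 0:
        raise InputContractError("empty feature sequence")
    labels, snaps = model.decision_path_(features)
    return list(zip(labels.tolist(), [s.copy() for s in snaps]))
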