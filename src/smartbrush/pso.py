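"""Global-best particle swarm optimization of the RPNN hyperparameters.

The swarm searches the triple (log10 sigma-scale, delta, K): a
multiplicative scale on all per-class kernel widths, the memory forgetting
factor, and the memory-length gain.  Fitness is frame-level accuracy of the
memory-smoothed classifier on held-out validation sessions, so the tuned
triple trades kernel smoothness against temporal smoothing on data with the
stream structure the classifier will actually see.

Default swarm constants follow the usual inertia-weight PSO: w = 0.30,
c1 = c2 = 2.0, 50 particles, 100 iterations, dimension 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .errors import ConfigError, EvaluationError
from .pnn import PNNClassifier
from .rpnn import RPNNClassifier

DEFAULT_BOUNDS = ((-1.0, 1.0), (0.0, 0.9), (0.1, 10.0))
DEFAULT_TRIPLE = (0.0, 0.2, 1.0)  # sigma-scale 10^0, delta 0.2, K 1.0


@dataclass
class PsoConfig:
    """Swarm constants; the defaults are the standard initial values."""

    w: float = 0.30
    c1: float = 2.0
    c2: float = 2.0
    n_particles: int = 50
    n_iters: int = 100
    dim: int = 3
    bounds: tuple = DEFAULT_BOUNDS
    seed: int = 0
    velocity_clamp: float = 0.5  # fraction of (hi - lo) per dimension
    init_positions: tuple = ()  # optional particles seeded into the swarm

    def __post_init__(self):
        if self.n_particles < 2:
            raise ConfigError("n_particles must be >= 2")
        if len(self.bounds) != self.dim:
            raise ConfigError(f"need {self.dim} bounds, got {len(self.bounds)}")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigError(f"invalid bound ({lo}, {hi}): lo must be < hi")


@dataclass
class PsoResult:
    best_position: np.ndarray
    best_score: float
    history: list = field(default_factory=list)


def optimize(fitness, config: PsoConfig) -> PsoResult:
    """Maximize ``fitness`` over the bounded box with global-best PSO.

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);  x <- clip(x + v).
    The per-iteration history of the global best score is monotone
    non-decreasing by construction; the run is fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    vmax = config.velocity_clamp * span

    x = lo + rng.random((config.n_particles, config.dim)) * span
    for i, pos in enumerate(config.init_positions):
        if i < config.n_particles:
            x[i] = np.clip(np.asarray(pos, dtype=float), lo, hi)
    v = np.zeros_like(x)

    def evaluate(pos: np.ndarray) -> float:
        score = float(fitness(pos))
        if not np.isfinite(score):
            raise EvaluationError(f"non-finite fitness {score} at position {pos.tolist()}")
        return score

    scores = np.array([evaluate(p) for p in x])
    pbest, pbest_scores = x.copy(), scores.copy()
    g = int(np.argmax(pbest_scores))
    gbest, gbest_score = pbest[g].copy(), float(pbest_scores[g])
    history = [gbest_score]

    for _ in range(config.n_iters):
        r1 = rng.random((config.n_particles, config.dim))
        r2 = rng.random((config.n_particles, config.dim))
        v = config.w * v + config.c1 * r1 * (pbest - x) + config.c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        scores = np.array([evaluate(p) for p in x])
        improved = scores > pbest_scores
        pbest[improved] = x[improved]
        pbest_scores[improved] = scores[improved]
        g = int(np.argmax(pbest_scores))
        if pbest_scores[g] > gbest_score:
            gbest, gbest_score = pbest[g].copy(), float(pbest_scores[g])
        history.append(gbest_score)
    return PsoResult(best_position=gbest, best_score=gbest_score, history=history)


def _as_xy(session):
    """Coerce a session to an (X, y) pair of arrays."""
    if hasattr(session, "xy"):
        return session.xy()
    X, y = session
    return np.asarray(X, dtype=float), np.asarray(y)


def labeled_xy(sessions, ignore_label=0):
    """Stack the labeled frames of many sessions into one (X, y) pair."""
    xs, ys = [], []
    for session in sessions:
        X, y = _as_xy(session)
        mask = y != ignore_label
        xs.append(X[mask])
        ys.append(y[mask])
    return np.vstack(xs), np.concatenate(ys)


def session_accuracy(model: RPNNClassifier, sessions, ignore_label=0) -> float:
    """Frame-level accuracy over sessions, memory reset per session.

    Frames labeled ``ignore_label`` (inter-region transitions, where the
    ground truth is neither region) are excluded from the count; the memory
    state still evolves through them.
    """
    correct = total = 0
    for session in sessions:
        X, y = _as_xy(session)
        pred = model.predict(X)
        mask = y != ignore_label
        correct += int(np.sum(pred[mask] == y[mask]))
        total += int(mask.sum())
    return correct / total if total else 0.0


def apply_triple(model: RPNNClassifier, triple) -> RPNNClassifier:
    """Shallow-copy the fitted model with a (log10 sigma-scale, delta, K)."""
    import copy

    log_scale, delta, k = (float(t) for t in triple)
    out = copy.copy(model)
    out.pnn_ = copy.copy(model.pnn_)
    out.pnn_.sigma_scale = 10.0 ** log_scale
    out.delta = delta
    out.k = k
    return out


def tune_rpnn(
    train_sessions,
    val_sessions,
    base: PNNClassifier | None = None,
    config: PsoConfig | None = None,
    fitted: RPNNClassifier | None = None,
) -> tuple[RPNNClassifier, PsoResult]:
    """Fit the PNN on the training sessions and PSO-tune (sigma, delta, K).

    The default triple is injected as one initial particle so the tuned
    model can never score below the untuned default on the validation set.
    If the validation sessions miss a training class a coverage warning is
    emitted (not fatal).  Returns the tuned fitted model and the PSO trace.
    """
    import warnings

    config = config or PsoConfig()
    if not config.init_positions:
        import dataclasses

        config = dataclasses.replace(config, init_positions=(DEFAULT_TRIPLE,))

    if fitted is None:
        X, y = labeled_xy(train_sessions)
        fitted = RPNNClassifier(pnn=base).fit(X, y)

    val_labels = np.unique(np.concatenate([_as_xy(s)[1] for s in val_sessions]))
    missing = set(fitted.classes_.tolist()) - set(val_labels.tolist())
    if missing:
        warnings.warn(f"validation sessions miss classes {sorted(missing)}", stacklevel=2)

    def fitness(pos):
        return session_accuracy(apply_triple(fitted, pos), val_sessions)

    result = optimize(fitness, config)
    return apply_triple(fitted, result.best_position), result
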