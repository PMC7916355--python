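"""Probabilistic neural network (Specht-style Gaussian-Parzen classifier).

Four conceptual layers: input, pattern (one Gaussian kernel per stored
training vector), summation (per-class kernel-density sums), output
(argmax).  The posterior for class c at query x is

    P_c(x) ∝ prior_c * (1/n_c) * sum_j exp(-||x - x_cj||^2 / (2 sigma_c^2))

with a per-class smoothing width sigma_c.  Training stores the patterns;
there is no iterative weight fitting, which is what makes incremental
pattern addition (and hence user personalization) cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DimensionError

VARIANCE_FLOOR = 1e-8
_CHUNK = 512  # query rows per distance block, bounds peak memory


class Standardizer:
    """Z-scoring with a variance floor.

    Columns whose variance falls below ``VARIANCE_FLOOR`` are flagged and
    scaled by 1 instead, so a constant feature maps to exactly zero rather
    than amplified noise.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None
        self.zero_variance_ = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        var = X.var(axis=0)
        self.zero_variance_ = var < VARIANCE_FLOOR
        self.scale_ = np.where(self.zero_variance_, 1.0, np.sqrt(var))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def _nearest_neighbor_sigma(X: np.ndarray) -> float:
    """Mean distance of each pattern to its nearest same-class neighbor."""
    if len(X) < 2:
        return np.nan
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


class PNNClassifier(ClassifierMixin, BaseEstimator):
    """Probabilistic neural network classifier.

    Parameters
    ----------
    sigma : float, array-like or None
        Smoothing width(s).  None (default) initializes per-class widths to
        the mean within-class nearest-neighbor distance in standardized
        feature space; a scalar is shared by all classes; an array gives one
        width per class (in ``classes_`` order).
    sigma_scale : float
        Multiplicative factor applied to the widths (the knob the swarm
        optimizer tunes).
    priors : "frequency" or "uniform"
        Class priors from training frequencies or uniform.
    standardize : bool
        Z-score features with training statistics (variance floor 1e-8).
    max_patterns_per_class : int or None
        Optional seeded per-class subsample cap on stored patterns.
    random_state : int or None
        Seed for the subsampling draw.

    Attributes
    ----------
    classes_ : sorted class labels.
    patterns_ : stored (standardized) training vectors, shape (n, d).
    pattern_labels_ : class index (into ``classes_``) per stored pattern.
    sigma_ : per-class smoothing widths.
    priors_ : per-class prior probabilities (sum to 1).
    scaler_ : fitted :class:`Standardizer` (identity stats if disabled).
    """

    def __init__(
        self,
        sigma=None,
        sigma_scale: float = 1.0,
        priors: str = "frequency",
        standardize: bool = True,
        max_patterns_per_class=None,
        random_state=None,
    ):
        self.sigma = sigma
        self.sigma_scale = sigma_scale
        self.priors = priors
        self.standardize = standardize
        self.max_patterns_per_class = max_patterns_per_class
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {X.shape}")
        if len(X) != len(y):
            raise DimensionError(f"X has {len(X)} rows but y has {len(y)} labels")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 1:
            raise DimensionError("no classes in y")

        self.scaler_ = Standardizer()
        if self.standardize:
            Xs = self.scaler_.fit_transform(X)
        else:
            self.scaler_.mean_ = np.zeros(X.shape[1])
            self.scaler_.scale_ = np.ones(X.shape[1])
            self.scaler_.zero_variance_ = np.zeros(X.shape[1], dtype=bool)
            Xs = X.copy()

        rng = np.random.default_rng(self.random_state)
        patterns, labels = [], []
        for ci, c in enumerate(self.classes_):
            Xc = Xs[y == c]
            cap = self.max_patterns_per_class
            if cap is not None and len(Xc) > cap:
                Xc = Xc[rng.choice(len(Xc), size=cap, replace=False)]
            patterns.append(Xc)
            labels.append(np.full(len(Xc), ci))
        self.patterns_ = np.vstack(patterns)
        self.pattern_labels_ = np.concatenate(labels)
        self._refresh_derived(class_counts_raw=np.array([np.sum(y == c) for c in self.classes_]))
        self.sigma_ = self._initial_sigma()
        return self

    def _refresh_derived(self, class_counts_raw=None):
        counts = np.bincount(self.pattern_labels_, minlength=len(self.classes_))
        if np.any(counts == 0):
            missing = self.classes_[counts == 0]
            raise DimensionError(f"classes with no stored pattern: {missing.tolist()}")
        self.class_counts_ = counts
        prior_counts = class_counts_raw if class_counts_raw is not None else counts
        if self.priors == "uniform":
            self.priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
        else:
            self.priors_ = prior_counts / prior_counts.sum()

    def _initial_sigma(self) -> np.ndarray:
        sig = np.empty(len(self.classes_))
        if self.sigma is not None:
            sig[:] = np.asarray(self.sigma, dtype=float)
        else:
            for ci in range(len(self.classes_)):
                sig[ci] = _nearest_neighbor_sigma(self.patterns_[self.pattern_labels_ == ci])
            fallback = np.nanmean(sig) if np.any(np.isfinite(sig)) else 1.0
            sig = np.where(np.isfinite(sig) & (sig > 0), sig, max(fallback, 1e-6))
        return np.maximum(sig, 1e-6)

    # ------------------------------------------------------- incremental add

    def add_patterns(self, X, y) -> "PNNClassifier":
        """Return a new model with extra labeled patterns appended.

        Priors are re-derived from the new pattern counts; smoothing widths
        of existing classes are kept (new classes get the nearest-neighbor
        heuristic).  The receiver is not mutated.
        """
        check_is_fitted(self, "patterns_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        import copy

        new = copy.deepcopy(self)
        if len(X) == 0:
            return new
        if X.ndim != 2 or X.shape[1] != self.patterns_.shape[1]:
            raise DimensionError(
                f"new patterns have dimension {X.shape[1] if X.ndim == 2 else X.ndim}, "
                f"model expects {self.patterns_.shape[1]}"
            )
        Xs = self.scaler_.transform(X)
        old_classes = list(self.classes_)
        all_classes = np.unique(np.concatenate([self.classes_, np.unique(y)]))
        remap = {c: i for i, c in enumerate(all_classes)}
        new.classes_ = all_classes
        new.pattern_labels_ = np.array(
            [remap[old_classes[ci]] for ci in self.pattern_labels_]
            + [remap[c] for c in y]
        )
        new.patterns_ = np.vstack([self.patterns_, Xs])
        sigma = np.full(len(all_classes), np.nan)
        for ci, c in enumerate(old_classes):
            sigma[remap[c]] = self.sigma_[ci]
        for c in np.unique(y):
            if c not in old_classes:
                est = _nearest_neighbor_sigma(new.patterns_[new.pattern_labels_ == remap[c]])
                sigma[remap[c]] = est if np.isfinite(est) and est > 0 else np.nanmean(self.sigma_)
        new.sigma_ = np.maximum(sigma, 1e-6)
        new._refresh_derived()
        return new

    # ------------------------------------------------------------- inference

    def _class_log_density(self, X: np.ndarray) -> np.ndarray:
        """Log of prior-weighted per-class kernel mixture, shape (n, C)."""
        sig = self.sigma_ * self.sigma_scale
        n = len(X)
        out = np.empty((n, len(self.classes_)))
        log_prior = np.log(self.priors_)
        with np.errstate(divide="ignore"):
            for start in range(0, n, _CHUNK):
                block = X[start : start + _CHUNK]
                d2 = cdist(block, self.patterns_, "sqeuclidean")
                for ci in range(len(self.classes_)):
                    cols = self.pattern_labels_ == ci
                    logk = -d2[:, cols] / (2.0 * sig[ci] ** 2)
                    out[start : start + len(block), ci] = (
                        logsumexp(logk, axis=1)
                        - np.log(self.class_counts_[ci])
                        + log_prior[ci]
                    )
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class probabilities; rows sum to 1.

        If every kernel underflows to zero mass at a query (all -inf in the
        log domain) the posterior falls back to the class priors.
        """
        check_is_fitted(self, "patterns_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.patterns_.shape[1]:
            raise DimensionError(
                f"query dimension {X.shape[1]} != model dimension {self.patterns_.shape[1]}"
            )
        logp = self._class_log_density(self.scaler_.transform(X))
        dead = ~np.isfinite(logp).any(axis=1)
        logp[dead] = np.log(self.priors_)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Argmax of the posterior; ties break to the lowest class label."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def n_parameters(self) -> int:
        """Stored scalar count: pattern entries + C widths + C priors."""
        check_is_fitted(self, "patterns_")
        return int(self.patterns_.size + 2 * len(self.classes_))


# ------------------------------------------------------- functional wrappers


def fit(X, y, **kwargs) -> PNNClassifier:
    return PNNClassifier(**kwargs).fit(X, y)


def posterior(model: PNNClassifier, x) -> np.ndarray:
    p = model.predict_proba(np.atleast_2d(x))
    return p[0] if np.asarray(x).ndim == 1 else p


def predict(model: PNNClassifier, x):
    y = model.predict(np.atleast_2d(x))
    return y[0] if np.asarray(x).ndim == 1 else y


def add_patterns(model: PNNClassifier, X, y) -> PNNClassifier:
    return model.add_patterns(X, y)
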