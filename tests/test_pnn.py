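"""PNN classifier vs an independent brute-force kernel-sum oracle."""

import numpy as np
import pytest

from smartbrush.errors import DimensionError
from smartbrush.pnn import PNNClassifier, Standardizer, posterior

from conftest import brute_force_posterior


def random_instance(rng, n_classes, n_patterns, dim=3):
    """A random fitted model (no standardization, explicit sigma) plus its
    raw ingredients for the oracle."""
    labels = rng.integers(1, n_classes + 1, n_patterns)
    # ensure every class occurs
    labels[:n_classes] = np.arange(1, n_classes + 1)
    X = rng.normal(0, 2.0, (n_patterns, dim))
    sigma = rng.uniform(0.3, 2.0, n_classes)
    model = PNNClassifier(sigma=sigma, standardize=False).fit(X, labels)
    return model, X, labels, sigma


class TestPosteriorOracle:
    def test_matches_brute_force_on_random_instances(self, rng):
        """>=100 random instances (<=50 patterns, <=5 classes) within 1e-12."""
        worst = 0.0
        for _ in range(100):
            C = int(rng.integers(2, 6))
            n = int(rng.integers(C, 51))
            model, X, labels, sigma = random_instance(rng, C, n)
            x = rng.normal(0, 2.0, 3)
            p = model.predict_proba(x[None, :])[0]
            p_ref = brute_force_posterior(
                x, X, labels, model.classes_, sigma, model.priors_
            )
            worst = max(worst, float(np.abs(p - p_ref).max()))
        assert worst < 1e-12

    def test_predict_agrees_with_oracle_argmax(self, rng):
        model, X, labels, sigma = random_instance(rng, 3, 12)
        queries = rng.normal(0, 2.0, (100, 3))
        for x in queries:
            p_ref = brute_force_posterior(
                x, X, labels, model.classes_, sigma, model.priors_
            )
            assert model.predict(x[None, :])[0] == model.classes_[np.argmax(p_ref)]

    def test_kernel_peak_at_stored_pattern(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        model = PNNClassifier(sigma=0.1, standardize=False).fit(X, [1, 2])
        p = model.predict_proba([[0.0, 0.0]])[0]
        assert model.classes_[np.argmax(p)] == 1 and p[0] > 0.99

    def test_mirror_symmetry_gives_half_half(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        model = PNNClassifier(sigma=1.0, standardize=False).fit(X, [1, 2])
        np.testing.assert_allclose(
            model.predict_proba([[0.0, 0.0]])[0], [0.5, 0.5], atol=1e-12
        )

    def test_posterior_sums_to_one_nonnegative(self, rng):
        model, *_ = random_instance(rng, 4, 30)
        P = model.predict_proba(rng.normal(0, 5.0, (50, 3)))
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_underflow_falls_back_to_priors(self):
        X = np.array([[0.0], [1.0], [1.0]])
        model = PNNClassifier(sigma=1e-3, standardize=False).fit(X, [1, 2, 2])
        p = model.predict_proba([[1e200]])[0]
        np.testing.assert_allclose(p, model.priors_, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        model, *_ = random_instance(rng, 2, 10)
        with pytest.raises(DimensionError):
            model.predict_proba(np.zeros((1, 5)))


class TestFit:
    def test_two_singleton_classes(self):
        model = PNNClassifier().fit(np.array([[0.0], [1.0]]), [1, 2])
        assert len(model.patterns_) == 2
        np.testing.assert_allclose(model.priors_, [0.5, 0.5])

    def test_frequency_priors(self):
        X = np.zeros((4, 2))
        model = PNNClassifier(sigma=1.0).fit(X, [1, 1, 1, 2])
        np.testing.assert_allclose(model.priors_, [0.75, 0.25])

    def test_protocol_scale_pattern_count(self, rng):
        """15 classes x 2000 training vectors store 30,000 patterns."""
        y = np.repeat(np.arange(1, 16), 2000)
        X = rng.normal(0, 1, (len(y), 3)) + y[:, None]
        model = PNNClassifier().fit(X, y)
        assert len(model.patterns_) == 30_000
        assert model.n_parameters() == 30_000 * 3 + 15 + 15

    def test_sigma_to_zero_limit_is_nearest_neighbor(self, rng):
        X = rng.normal(0, 1, (40, 2))
        X[20:] += 8.0
        y = np.array([1] * 20 + [2] * 20)
        model = PNNClassifier(sigma=1e-3, standardize=False).fit(X, y)
        queries = rng.normal(0.5, 3.0, (30, 2))
        from scipy.spatial.distance import cdist

        nn = y[np.argmin(cdist(queries, X), axis=1)]
        np.testing.assert_array_equal(model.predict(queries), nn)

    def test_tie_breaks_to_lowest_class(self):
        X = np.array([[-1.0], [1.0]])
        model = PNNClassifier(sigma=1.0, standardize=False).fit(X, [1, 2])
        assert model.predict([[0.0]])[0] == 1


class TestAddPatterns:
    def _base(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        return PNNClassifier(sigma=1.0, standardize=False).fit(X, [1, 2]), X

    def test_add_nothing_is_identity(self):
        model, _ = self._base()
        out = model.add_patterns(np.empty((0, 2)), np.empty(0, dtype=int))
        np.testing.assert_array_equal(out.patterns_, model.patterns_)
        np.testing.assert_allclose(out.priors_, model.priors_)

    def test_priors_rederived(self):
        model, _ = self._base()
        out = model.add_patterns([[5.0, 4.0]], [2])
        np.testing.assert_allclose(out.priors_, [1 / 3, 2 / 3])

    def test_refit_equivalence(self, rng):
        X1 = rng.normal(0, 1, (20, 3))
        y1 = rng.integers(1, 4, 20)
        y1[:3] = [1, 2, 3]
        X2 = rng.normal(0, 1, (10, 3))
        y2 = rng.integers(1, 4, 10)
        inc = PNNClassifier(sigma=0.8, standardize=False).fit(X1, y1).add_patterns(X2, y2)
        scratch = PNNClassifier(sigma=0.8, standardize=False).fit(
            np.vstack([X1, X2]), np.concatenate([y1, y2])
        )
        Q = rng.normal(0, 1, (25, 3))
        np.testing.assert_allclose(
            inc.predict_proba(Q), scratch.predict_proba(Q), atol=1e-12
        )

    def test_new_class_extends_model(self):
        model, _ = self._base()
        out = model.add_patterns([[9.0, 9.0]], [7])
        assert list(out.classes_) == [1, 2, 7]
        assert out.predict([[9.0, 9.0]])[0] == 7

    def test_source_not_mutated(self):
        model, _ = self._base()
        before = model.patterns_.copy()
        model.add_patterns([[1.0, 1.0]], [1])
        np.testing.assert_array_equal(model.patterns_, before)


class TestStandardizer:
    def test_constant_column_flagged_and_zeroed(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        sc = Standardizer().fit(X)
        assert sc.zero_variance_[0] and not sc.zero_variance_[1]
        out = sc.transform(X)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[:, 1].std(), 1.0, atol=1e-12)


def test_serialization_roundtrip(tmp_path, rng):
    from smartbrush import io
    from smartbrush.rpnn import RPNNClassifier

    X = rng.normal(0, 1, (30, 3))
    y = rng.integers(1, 4, 30)
    y[:3] = [1, 2, 3]
    model = RPNNClassifier(delta=0.3, k=2.0).fit(X, y)
    path = tmp_path / "model.rpnn"
    io.save_model(model, path, meta={"seed": 1})
    loaded = io.load_model(path)
    Q = rng.normal(0, 1, (10, 3))
    np.testing.assert_allclose(
        loaded.pnn_.predict_proba(Q), model.pnn_.predict_proba(Q), atol=1e-12
    )
    np.testing.assert_array_equal(loaded.predict(Q), model.predict(Q))
    assert loaded.delta == 0.3 and loaded.k == 2.0
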