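"""KNN velocity regression: oracle equivalence, LOO VAF, recovery."""

import numpy as np
import pytest

import myoknn as mk
from myoknn.decoder import (
    InsufficientDataError,
    KnnModel,
    UndefinedVafError,
    loo_vaf,
    predict,
    vaf,
)
from conftest import brute_force_knn


def _random_model(rng, n=300, k=50, eps=1e-9):
    X = rng.random((n, 16))
    T = rng.uniform(-1, 1, (n, 3))
    return KnnModel(train_features=X, train_targets=T, k=k, epsilon=eps)


class TestPredict:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            model = _random_model(rng)
            for _ in range(10):
                q = rng.random(16)
                expected = brute_force_knn(
                    model.train_features, model.train_targets, model.k,
                    model.epsilon, q,
                )
                np.testing.assert_allclose(predict(model, q), expected, atol=1e-10)

    def test_k_equals_one_returns_nearest_target(self, rng):
        model = _random_model(rng, n=50, k=1)
        q = rng.random(16)
        d = np.linalg.norm(model.train_features - q, axis=1)
        np.testing.assert_allclose(
            predict(model, q),
            np.clip(model.train_targets[np.argmin(d)], -1, 1),
            atol=1e-12,
        )

    def test_exact_match_dominates_as_epsilon_shrinks(self, rng):
        model = _random_model(rng, n=200, k=10, eps=1e-15)
        i = 17
        out = predict(model, model.train_features[i])
        np.testing.assert_allclose(out, np.clip(model.train_targets[i], -1, 1),
                                   atol=1e-6)

    def test_output_always_within_unit_cube(self, rng):
        model = _random_model(rng)
        out = predict(model, rng.random((200, 16)) * 5)
        assert np.all(np.abs(out) <= 1.0)

    def test_permuting_training_rows_preserves_predictions(self, rng):
        model = _random_model(rng)
        perm = rng.permutation(model.n_train)
        permuted = KnnModel(
            train_features=model.train_features[perm],
            train_targets=model.train_targets[perm],
            k=model.k,
            epsilon=model.epsilon,
        )
        q = rng.random((20, 16))
        np.testing.assert_allclose(
            predict(model, q), predict(permuted, q), atol=1e-10
        )

    def test_tie_break_by_training_index(self):
        """Duplicate training rows at the k-th distance: lower index wins."""
        X = np.zeros((4, 2))
        X[0] = X[1] = [1.0, 0.0]  # equidistant pair
        X[2] = [0.5, 0.0]
        X[3] = [5.0, 5.0]
        T = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 0, 0], [0.0, 0, 0]])
        model = KnnModel(train_features=X, train_targets=T, k=2)
        out = predict(model, np.zeros(2))
        # neighbors: row 2 (d=0.5) and row 0 (d=1, beats row 1 by index)
        w = np.array([1.0 / 0.5, 1.0])
        expected = (w[0] * T[2] + w[1] * T[0]) / w.sum()
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = _random_model(rng)
        with pytest.raises(ValueError, match="features"):
            predict(model, rng.random(5))

    def test_refit_gives_identical_predictions(self, trained_small):
        model = trained_small["model"]
        probe = model.train_features[::500]
        again = KnnModel(
            train_features=model.train_features,
            train_targets=model.train_targets,
            k=model.k,
            scale=model.scale,
        )
        np.testing.assert_array_equal(predict(model, probe), predict(again, probe))


class TestFitValidation:
    def test_n_below_k_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            _random_model(rng, n=99, k=100)

    def test_n_equal_k_valid(self, rng):
        model = _random_model(rng, n=100, k=100)
        assert np.all(np.abs(predict(model, rng.random(16))) <= 1)


class TestVaf:
    def test_perfect_predictions_give_100(self, rng):
        T = rng.uniform(-1, 1, (50, 3))
        np.testing.assert_allclose(vaf(T, T), 100.0)

    def test_mean_predictor_gives_0(self, rng):
        T = rng.uniform(-1, 1, (50, 3))
        P = np.tile(T.mean(axis=0), (50, 1))
        np.testing.assert_allclose(vaf(T, P), 0.0, atol=1e-9)

    def test_zero_variance_dof_errors_with_name(self, rng):
        T = rng.uniform(-1, 1, (50, 3))
        T[:, 1] = 0.3
        with pytest.raises(UndefinedVafError, match="1"):
            vaf(T, T)

    def test_loo_needs_spare_sample(self, rng):
        model = _random_model(rng, n=100, k=100)
        with pytest.raises(InsufficientDataError):
            loo_vaf(model)

    def test_loo_matches_manual_exclusion_on_small_model(self, rng):
        """Chunked LOO equals per-row prediction from an explicitly reduced model."""
        model = _random_model(rng, n=60, k=10)
        preds = []
        for i in range(model.n_train):
            keep = np.arange(60) != i
            sub = KnnModel(
                train_features=model.train_features[keep],
                train_targets=model.train_targets[keep],
                k=10,
                epsilon=model.epsilon,
            )
            preds.append(predict(sub, model.train_features[i]))
        expected = vaf(model.train_targets, np.asarray(preds))
        np.testing.assert_allclose(loo_vaf(model), expected, atol=1e-8)


class TestDecodingRecovery:
    def test_loo_vaf_high_on_default_synthetic_protocol(self, trained_small):
        """The full train stack decodes its own synthetic EMG well offline."""
        scores = loo_vaf(trained_small["model"])
        assert np.all(scores > 60.0)

    def test_held_out_cosine_similarity_exceeds_0_8(self, trained_small):
        """Parameter recovery: train on one synthetic session, decode EMG from
        a fresh seed; per-DOF cosine similarity of predicted vs true intent
        exceeds 0.8 at the intramuscular SNR preset."""
        cfg2 = mk.RunConfig(repetitions=1, generator_seed=77)
        held = mk.train_decoder(cfg2)
        model = trained_small["model"]
        feats = mk.apply_normalization(held["features"], trained_small["scale"])
        preds = predict(model, feats.values)
        true = held["true_intent"]
        # align: true intent is on the same 50 ms grid starting at 0.05 s,
        # features start at 0.2 s (frame end times)
        offset = np.searchsorted(true.times, feats.times[0] - 1e-9)
        truth = true.values[offset : offset + len(preds)]
        for d in range(3):
            t, p = truth[:, d], preds[:, d]
            cos = np.dot(t, p) / (np.linalg.norm(t) * np.linalg.norm(p))
            assert cos > 0.8, f"DOF {d} cosine {cos:.3f}"
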