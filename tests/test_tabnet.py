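"""Sparsemax, attentive steps, the classifier, search and baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stabsense.errors import TrainingError, ValidationError
from stabsense.tabnet import (
    SearchSpace,
    TabNetClassifier,
    TabNetConfig,
    attentive_step,
    hyperparameter_search,
    sparsemax,
    train_baselines,
    train_tabnet,
)


def simplex_projection_bruteforce(z):
    """Independent oracle: try every support set of the simplex projection."""
    n = len(z)
    best, best_dist = None, np.inf
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            s = list(support)
            tau = (z[s].sum() - 1) / len(s)
            p = np.zeros(n)
            p[s] = z[s] - tau
            if np.any(p[s] < -1e-12):
                continue
            p = np.maximum(p, 0)
            dist = np.sum((p - z) ** 2)
            if dist < best_dist - 1e-15:
                best, best_dist = p, dist
    return best


class TestSparsemax:
    @pytest.mark.parametrize(
        "z, expected",
        [
            ([1.0, 0.0, 0.0], [1.0, 0.0, 0.0]),
            ([0.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3]),
            ([0.5, 0.5], [0.5, 0.5]),
        ],
    )
    def test_reference_values(self, z, expected):
        assert np.allclose(sparsemax(z), expected)

    def test_matches_bruteforce_projection_on_1000_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            dim = int(rng.integers(2, 7))
            z = rng.standard_normal(dim) * rng.uniform(0.5, 3)
            assert np.allclose(sparsemax(z), simplex_projection_bruteforce(z), atol=1e-8)

    def test_invariant_to_constant_shifts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            z = rng.standard_normal(8)
            c = rng.uniform(-100, 100)
            assert np.allclose(sparsemax(z), sparsemax(z + c), atol=1e-9)

    def test_rows_sum_to_one_and_are_nonnegative(self):
        rng = np.random.default_rng(2)
        out = sparsemax(rng.standard_normal((200, 10)) * 3)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            sparsemax([])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=12),
        st.floats(-100, 100),
    )
    def test_output_lies_on_simplex_and_ignores_score_shifts(self, z, c):
        z = np.asarray(z)
        p = sparsemax(z)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(p, sparsemax(z + c), atol=1e-8)


class TestAttentiveStep:
    def test_neutral_prior_reduces_to_plain_sparsemax(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((4, 6))
        W = rng.standard_normal((6, 5))
        mask, _ = attentive_step(a, np.ones((4, 5)), W, gamma=1.0)
        assert np.allclose(mask, sparsemax(a @ W))

    def test_fully_used_feature_is_excluded_at_later_steps_with_unit_gamma(self):
        # step s: all attention lands on feature 0 -> its prior becomes 0;
        # at the next step another feature dominates, so feature 0 gets none
        a = np.array([[1.0]])
        W_first = np.array([[5.0, 0.0, 0.0]])
        mask1, prior = attentive_step(a, np.ones((1, 3)), W_first, gamma=1.0)
        assert np.allclose(mask1, [[1.0, 0.0, 0.0]])
        assert prior[0, 0] == pytest.approx(0.0)
        W_second = np.array([[4.0, 2.0, 0.5]])
        mask2, _ = attentive_step(a, prior, W_second, gamma=1.0)
        assert mask2[0, 0] == pytest.approx(0.0)
        assert mask2.sum() == pytest.approx(1.0)

    def test_mask_rows_always_sum_to_one(self):
        rng = np.random.default_rng(4)
        prior = rng.uniform(0, 1.3, size=(32, 7))
        mask, _ = attentive_step(rng.standard_normal((32, 5)), prior,
                                 rng.standard_normal((5, 7)), gamma=1.3)
        assert np.allclose(mask.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def separable_toy():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((400, 5))
    y = (X[:, 1] > 0.0).astype(int)
    X[:, 1] += np.where(y == 1, 0.25, -0.25)  # margin-separated
    return X, y


class TestClassifier:
    def test_single_step_aggregate_equals_its_mask(self, separable_toy):
        X, y = separable_toy
        model = TabNetClassifier(n_d=8, n_a=4, n_steps=1, gamma=1.3,
                                 max_epochs=3, random_state=0)
        model.fit(X, y)
        trace = model.explain(X[:20])
        assert len(trace.step_masks) == 1
        assert np.allclose(trace.aggregate, trace.step_masks[0], atol=1e-9)

    def test_duplicated_sample_gets_identical_logits(self, separable_toy):
        X, y = separable_toy
        model = TabNetClassifier(n_d=8, n_a=4, max_epochs=3, gamma=1.3, random_state=0)
        model.fit(X, y)
        doubled = np.vstack([X[:1], X[:1], X[1:40]])
        z = model.decision_function(doubled)
        assert z[0] == pytest.approx(z[1], abs=1e-12)

    def test_planted_relevant_feature_dominates_importance(self, separable_toy):
        X, y = separable_toy
        model = TabNetClassifier(n_d=16, n_a=8, gamma=1.3, lambda_sparse=1e-3,
                                 learning_rate=0.02, batch_size=64,
                                 max_epochs=30, random_state=0)
        model.fit(X, y)
        assert np.argmax(model.feature_importances_) == 1
        assert model.feature_importances_[1] > 0.4

    def test_capacity_sanity_on_separable_data(self, separable_toy):
        X, y = separable_toy
        model = TabNetClassifier(n_d=16, n_a=8, gamma=1.3, lambda_sparse=1e-3,
                                 learning_rate=0.02, batch_size=64,
                                 max_epochs=40, random_state=1)
        model.fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.97

    def test_training_is_deterministic_given_seed(self, separable_toy):
        X, y = separable_toy
        runs = []
        for _ in range(2):
            m = TabNetClassifier(n_d=8, n_a=4, max_epochs=6, gamma=1.3, random_state=3)
            m.fit(X[:300], y[:300], X_valid=X[300:], y_valid=y[300:])
            runs.append((m.valid_loss_history_, m.predict_proba(X[300:])[:, 1]))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_single_class_training_data_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        with pytest.raises(TrainingError):
            TabNetClassifier(max_epochs=2).fit(X, np.zeros(50))

    def test_mask_trace_invariants_on_random_inputs(self, separable_toy):
        X, y = separable_toy
        model = TabNetClassifier(n_d=8, n_a=4, n_steps=3, gamma=1.3,
                                 max_epochs=3, random_state=0)
        model.fit(X, y)
        trace = model.explain(np.random.default_rng(6).standard_normal((64, 5)))
        for mask in trace.step_masks:
            assert np.allclose(mask.sum(axis=1), 1.0, atol=1e-6)
            assert (mask >= 0).all()
        assert np.allclose(trace.aggregate.sum(axis=1), 1.0, atol=1e-6)
        assert trace.importance.sum() == pytest.approx(1.0, abs=1e-6)
        assert trace.sparsity_penalty >= 0.0

    def test_sparsity_penalty_is_zero_only_for_one_hot_masks(self):
        eps = 1e-10
        one_hot = np.array([[1.0, 0.0, 0.0]])
        entropy = -(one_hot * np.log(one_hot + eps)).sum()
        assert entropy == pytest.approx(0.0, abs=1e-6)
        diffuse = np.full((1, 3), 1 / 3)
        assert -(diffuse * np.log(diffuse + eps)).sum() > 1.0


class TestSearch:
    def _objective(self, X, y):
        def objective(cfg: TabNetConfig):
            # cheap deterministic surrogate of validation F1
            return -abs(np.log10(cfg.learning_rate) + 2) - 0.01 * cfg.n_steps

        return objective

    def test_singleton_search_returns_that_trial(self):
        space = SearchSpace(n_trials=1)
        best, log = hyperparameter_search(space, lambda cfg: 1.0, seed=0)
        assert len(log) == 1
        assert log.loc[0, "score"] == 1.0

    def test_samples_respect_bounds_and_log_is_complete(self):
        space = SearchSpace(n_trials=25)
        best, log = hyperparameter_search(space, self._objective(None, None), seed=1)
        assert ((log["learning_rate"] >= 1e-5) & (log["learning_rate"] <= 1e-1)).all()
        assert ((log["n_d"] >= 8) & (log["n_d"] <= 64)).all()
        assert ((log["n_steps"] >= 3) & (log["n_steps"] <= 10)).all()
        best_row = log.loc[log["score"].idxmax()]
        assert best.learning_rate == pytest.approx(best_row["learning_rate"])
        assert best_row["score"] == log["score"].max()

    def test_failed_trials_are_logged_and_skipped(self):
        calls = {"n": 0}

        def flaky(cfg):
            calls["n"] += 1
            if calls["n"] % 2:
                raise RuntimeError("boom")
            return float(calls["n"])

        best, log = hyperparameter_search(SearchSpace(n_trials=6), flaky, seed=2)
        assert (log["status"] != "ok").sum() == 3
        assert log["score"].max() == 6.0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValidationError):
            SearchSpace(n_d=(64, 8)).validate()


class TestBaselines:
    def test_gbdt_capacity_sanity(self, separable_toy):
        X, y = separable_toy
        model = train_baselines(X, y, kind="gbdt", seed=0)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_baselines_are_deterministic(self, separable_toy):
        X, y = separable_toy
        for kind in ("mlp", "gbdt"):
            a = train_baselines(X, y, kind=kind, seed=4).predict(X)
            b = train_baselines(X, y, kind=kind, seed=4).predict(X)
            assert np.array_equal(a, b)

    def test_mlp_collapses_on_extreme_imbalance_without_augmentation(self):
        rng = np.random.default_rng(7)
        n = 8000
        X = rng.standard_normal((n, 8))
        y = np.zeros(n, dtype=int)
        pos = rng.choice(n, 7, replace=False)
        y[pos] = 1
        X[pos] += 1.0  # mild signal, hopeless at 0.09% prevalence
        model = train_baselines(X, y, kind="mlp", seed=0)
        pred = model.predict(X)
        recall = pred[y == 1].mean()
        assert recall <= 0.2
        assert (pred == 0).mean() > 0.99


def test_save_load_round_trip_preserves_predictions(separable_toy, tmp_path):
    X, y = separable_toy
    model = TabNetClassifier(n_d=8, n_a=4, gamma=1.3, max_epochs=5, random_state=0)
    model.fit(X, y)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    loaded = TabNetClassifier.load(path)
    assert np.allclose(model.decision_function(X), loaded.decision_function(X))
    assert np.array_equal(model.predict(X), loaded.predict(X))


def test_train_tabnet_wrapper_validates_config(separable_toy):
    X, y = separable_toy
    with pytest.raises(ValidationError):
        train_tabnet(X, y, cfg=TabNetConfig(gamma=-1.0))
    model = train_tabnet(X[:200], y[:200], cfg=TabNetConfig(n_d=8, n_a=4, gamma=1.3, max_epochs=2))
    assert model.predict(X[:5]).shape == (5,)
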