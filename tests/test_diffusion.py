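"""Diffusion schedule algebra, constraint enforcement, generation quality."""

import numpy as np
import pandas as pd
import pytest

from stabsense.cohort import INFORMATIVE_FEATURES, default_cohort_spec, generate_cohort
from stabsense.diffusion import (
    AugmentationRecipe,
    AugmentedDataset,
    CategoricalSpec,
    ConstraintSet,
    NoiseQuery,
    TabularDiffusionGenerator,
    check_constraints,
    compose_augmented,
    forward_noise,
    make_schedule,
    marginal_fidelity,
    multinomial_forward,
)
from stabsense.errors import CompositionError, GenerationError, SchemaError, ValidationError


class TestSchedule:
    def test_single_step_product(self):
        s = make_schedule(1, beta_start=0.5, beta_end=0.5)
        assert s.alpha_bar[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("kind", ["linear", "cosine"])
    def test_alpha_bar_strictly_decreasing(self, kind):
        s = make_schedule(200, kind=kind)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert np.allclose(s.alpha, 1 - s.beta)

    def test_default_linear_schedule_ends_near_zero(self):
        s = make_schedule(1000)
        assert s.alpha_bar[-1] < 1e-3

    def test_nonpositive_T_rejected(self):
        with pytest.raises(ValidationError):
            make_schedule(0)


class TestForwardNoise:
    def test_no_noise_limit_returns_input(self):
        s = make_schedule(1, beta_start=1e-12, beta_end=1e-12)
        x0 = np.array([1.5, -2.0])
        out = forward_noise(NoiseQuery(x0=x0, t=1, eps=np.ones(2)), s)
        assert np.allclose(out, x0, atol=1e-5)

    def test_closed_form_value(self):
        # two steps of beta=0.5 give alpha_bar = 0.25
        s = make_schedule(2, beta_start=0.5, beta_end=0.5)
        out = forward_noise(NoiseQuery(x0=np.array([2.0, -2.0]), t=2, eps=np.ones(2)), s)
        expected = np.array([1 + np.sqrt(0.75), -1 + np.sqrt(0.75)])
        assert np.allclose(out, expected)

    def test_moments_match_the_closed_form(self):
        s = make_schedule(50)
        rng = np.random.default_rng(0)
        x0 = np.array([2.0, -1.0])
        t = 30
        draws = np.stack(
            [forward_noise(NoiseQuery(x0, t, rng.standard_normal(2)), s) for _ in range(10_000)]
        )
        ab = s.alpha_bar[t - 1]
        assert np.allclose(draws.mean(axis=0), np.sqrt(ab) * x0, atol=0.05)
        assert np.allclose(draws.var(axis=0), 1 - ab, atol=0.05)

    def test_closed_form_matches_iterated_single_steps(self):
        # the single-step recursion x_t = sqrt(a_t) x_{t-1} + sqrt(1-a_t) e_t
        # implies mean sqrt(abar_t) x0 and variance 1 - abar_t; check the
        # variance recursion exactly and the sample paths in distribution
        s = make_schedule(50)
        var = 0.0
        for t in range(50):
            var = s.alpha[t] * var + (1 - s.alpha[t])
            assert var == pytest.approx(1 - s.alpha_bar[t], abs=1e-12)
        rng = np.random.default_rng(1)
        x0 = 1.7
        iterated = np.full(20_000, x0)
        for t in range(50):
            iterated = np.sqrt(s.alpha[t]) * iterated + np.sqrt(1 - s.alpha[t]) * rng.standard_normal(
                iterated.shape
            )
        assert iterated.mean() == pytest.approx(np.sqrt(s.alpha_bar[-1]) * x0, abs=0.02)
        assert iterated.var() == pytest.approx(1 - s.alpha_bar[-1], abs=0.02)

    def test_out_of_range_timestep_raises(self):
        s = make_schedule(10)
        with pytest.raises(IndexError):
            forward_noise(NoiseQuery(np.zeros(2), 11, np.zeros(2)), s)


class TestMultinomialForward:
    def test_tiny_beta_leaves_distribution_unchanged(self):
        s = make_schedule(1, beta_start=1e-12, beta_end=1e-12)
        p = multinomial_forward(CategoricalSpec(3, np.array([1.0, 0, 0])), 1, s)
        assert np.allclose(p, [1, 0, 0], atol=1e-9)

    def test_beta_one_limit_is_uniform(self):
        s = make_schedule(1, beta_start=1 - 1e-12, beta_end=1 - 1e-12)
        p = multinomial_forward(CategoricalSpec(4, np.array([0, 0, 1.0, 0])), 1, s)
        assert np.allclose(p, 0.25, atol=1e-9)

    def test_half_flattening_two_categories(self):
        s = make_schedule(1, beta_start=0.5, beta_end=0.5)
        p = multinomial_forward(CategoricalSpec(2, np.array([1.0, 0.0])), 1, s)
        assert np.allclose(p, [0.75, 0.25])

    def test_repeated_transitions_converge_to_uniform(self):
        s = make_schedule(800, beta_start=0.02, beta_end=0.02)
        p = np.array([1.0, 0, 0, 0, 0])
        for t in range(1, 801):
            p = multinomial_forward(CategoricalSpec(5, p), t, s)
        assert np.max(np.abs(p - 0.2)) < 1e-6

    def test_fewer_than_two_categories_rejected(self):
        s = make_schedule(5)
        with pytest.raises(ValidationError):
            multinomial_forward(CategoricalSpec(1, np.array([1.0])), 1, s)


class TestConstraints:
    def test_in_tolerance_record_passes(self):
        rec = {f: 1.0 for f in INFORMATIVE_FEATURES}
        rec.update(TS=12.6, Fat=4.0, SNF=8.7)
        assert check_constraints(rec) is True

    def test_mass_balance_violation_fails(self):
        rec = {f: 1.0 for f in INFORMATIVE_FEATURES}
        rec.update(TS=13.5, Fat=4.0, SNF=8.7)
        assert check_constraints(rec) is False

    def test_nonpositive_selected_feature_fails(self):
        rec = {f: 1.0 for f in INFORMATIVE_FEATURES}
        rec.update(TS=12.6, Fat=4.0, SNF=8.7, Protein=-0.01)
        assert check_constraints(rec) is False

    def test_missing_field_raises_schema_error(self):
        with pytest.raises(SchemaError, match="SNF"):
            check_constraints({"TS": 12.0, "Fat": 4.0})


@pytest.fixture(scope="module")
def milk_positive_generator():
    table = generate_cohort(default_cohort_spec(n_records=12_800, seed=13))
    pos = table[table["ES"] == 1][INFORMATIVE_FEATURES].reset_index(drop=True)
    gen = TabularDiffusionGenerator(T=200, epochs=400, beta_end=0.1, random_state=0)
    gen.fit(pos)
    return gen, pos


class TestGenerator:
    def test_toy_distribution_recovery_within_ten_percent(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"x": rng.normal(5.0, 2.0, 500), "y": rng.normal(-3.0, 0.5, 500)})
        gen = TabularDiffusionGenerator(T=200, epochs=800, batch_size=128,
                                        beta_end=0.1, random_state=0)
        gen.fit(train)
        out = gen.sample(2000, random_state=1)
        for col, mu, sd in [("x", 5.0, 2.0), ("y", -3.0, 0.5)]:
            assert out[col].mean() == pytest.approx(mu, abs=0.1 * abs(mu))
            assert out[col].std() == pytest.approx(sd, rel=0.10)

    def test_loss_decreases_in_moving_average(self, milk_positive_generator):
        gen, _ = milk_positive_generator
        loss = np.asarray(gen.loss_history_)
        assert loss[-20:].mean() < loss[:5].mean()

    def test_same_seed_yields_identical_parameters(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame({"x": rng.normal(size=100)})
        fits = []
        for _ in range(2):
            g = TabularDiffusionGenerator(T=20, epochs=30, random_state=7)
            g.fit(train)
            fits.append(np.concatenate([p.data.ravel() for p in g._net.params()]))
        assert np.array_equal(fits[0], fits[1])

    def test_every_sampled_record_satisfies_constraints(self, milk_positive_generator):
        gen, pos = milk_positive_generator
        out = gen.sample(300, random_state=3)
        assert len(out) == 300
        assert check_constraints(out).all()
        assert 0 < gen.acceptance_rate_ <= 1

    def test_sampling_is_deterministic_given_seed(self, milk_positive_generator):
        gen, _ = milk_positive_generator
        a = gen.sample(50, random_state=9)
        b = gen.sample(50, random_state=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unsatisfiable_constraints_raise_with_violation_stats(self, milk_positive_generator):
        gen, _ = milk_positive_generator
        impossible = ConstraintSet(mass_balance_tol=1e-9)
        with pytest.raises(GenerationError) as err:
            gen.sample(50, constraints=impossible, random_state=0, max_attempts_factor=3)
        assert err.value.violation_freq["mass_balance"] > 0.9

    def test_marginal_overlap_on_unimodal_features(self, milk_positive_generator):
        gen, pos = milk_positive_generator
        out = gen.sample(1000, random_state=5)
        fid = marginal_fidelity(out, pos, n_bins=20)
        assert (fid["overlap"] > 0.6).all()
        assert fid.loc["Protein", "overlap"] > 0.8
        assert (fid["ks_distance"] < 0.25).all()

    def test_categorical_path_recovers_category_frequencies(self):
        rng = np.random.default_rng(4)
        n = 400
        train = pd.DataFrame(
            {
                "Protein": rng.normal(3.2, 0.15, n),
                "AD1": (rng.random(n) < 0.30).astype(int),
                "AD2": (rng.random(n) < 0.70).astype(int),
            }
        )
        gen = TabularDiffusionGenerator(
            T=100, epochs=800, batch_size=128, beta_end=0.2,
            categorical_features=["AD1", "AD2"], random_state=0
        )
        gen.fit(train)
        out = gen.sample(1000, random_state=1)
        assert set(out["AD1"].unique()) <= {0, 1}
        assert out["AD1"].mean() == pytest.approx(0.30, abs=0.10)
        assert out["AD2"].mean() == pytest.approx(0.70, abs=0.10)


class TestFidelity:
    def test_identical_samples_score_perfectly(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"a": rng.normal(size=300)})
        fid = marginal_fidelity(table, table.copy())
        assert fid.loc["a", "overlap"] == pytest.approx(1.0)
        assert fid.loc["a", "ks_distance"] == pytest.approx(0.0)

    def test_disjoint_supports_score_zero_overlap(self):
        a = pd.DataFrame({"a": np.linspace(0, 1, 100)})
        b = pd.DataFrame({"a": np.linspace(10, 11, 100)})
        fid = marginal_fidelity(a, b)
        assert fid.loc["a", "overlap"] == pytest.approx(0.0)
        assert fid.loc["a", "ks_distance"] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        table = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValidationError):
            marginal_fidelity(table.iloc[:0], table)


def _frame(n, cols=("Protein", "TS", "SNF", "Fat")):
    rng = np.random.default_rng(n)
    return pd.DataFrame({c: rng.normal(size=n) for c in cols})


class TestComposition:
    def test_reference_counts(self):
        aug = compose_augmented(_frame(842), _frame(3368), _frame(20_000))
        assert aug.n_pos_total == 5052
        assert aug.n_neg == 15_156
        assert aug.n_dup_pos == 842 and aug.n_gen_pos == 3368

    def test_recipe_arithmetic_small(self):
        aug = compose_augmented(_frame(10), _frame(40), _frame(500))
        assert aug.n_pos_total == 60
        assert aug.n_neg == 180

    def test_identity_composition(self):
        recipe = AugmentationRecipe(duplicate_real=False, gen_per_real=0, neg_per_pos=0)
        aug = compose_augmented(_frame(25), _frame(25).iloc[:0], _frame(5), recipe)
        assert aug.n_pos_total == 25
        assert len(aug) == 25

    def test_total_length_conservation(self):
        aug = compose_augmented(_frame(30), _frame(120), _frame(800))
        assert aug.n_pos_total + aug.n_neg == len(aug)
        counts = aug.records["source"].value_counts()
        assert counts["generated"] == 120 and counts["negative"] == aug.n_neg

    def test_insufficient_negatives_raise(self):
        with pytest.raises(CompositionError):
            compose_augmented(_frame(100), _frame(400), _frame(100))

    def test_mismatched_generated_count_raises(self):
        with pytest.raises(CompositionError):
            compose_augmented(_frame(100), _frame(399), _frame(5000))
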