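import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asdmetry.diagnosis import (
    GAConfig,
    RecordTable,
    bayes_posterior,
    expected_copies,
    fitness_sigmoid,
    ga_select_features,
    joint_probability,
    nb_fit,
    nb_predict,
    synthetic_records,
)


class TestFitnessSigmoid:
    def test_midpoint_is_half(self):
        assert fitness_sigmoid(0.0) == pytest.approx(0.5)
        assert fitness_sigmoid(0.0, "conventional") == pytest.approx(0.5)

    def test_printed_form_decreases(self):
        # as printed the map is decreasing: large a scores near 0
        assert fitness_sigmoid(1.0) == pytest.approx(0.26894, abs=1e-5)
        assert fitness_sigmoid(50.0) < 1e-20

    def test_conventional_form_increases(self):
        assert fitness_sigmoid(1.0, "conventional") == pytest.approx(0.73106, abs=1e-5)


class TestExpectedCopies:
    @pytest.mark.parametrize(
        "fitness,n,expected",
        [
            ([1.0, 1.0, 1.0, 1.0], 4, [1, 1, 1, 1]),
            ([3.0, 1.0], 4, [3, 1]),
        ],
    )
    def test_exact_proportions(self, fitness, n, expected):
        assert expected_copies(fitness, n).tolist() == expected

    def test_largest_remainder_preserves_population_size(self):
        counts = expected_copies([1.0, 1.0, 1.0], 4)
        assert counts.sum() == 4
        assert counts.min() >= 1

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12),
        st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_counts_always_sum_to_population(self, fitness, n):
        assert expected_copies(fitness, n).sum() == n


class TestNaiveBayes:
    def test_single_class_prior_is_one(self):
        table = RecordTable(
            pd.DataFrame({"f": [0, 1, 0], "disease": ["a", "a", "a"]}), "disease"
        )
        model = nb_fit(table, smoothing=0.0)
        assert model.priors["a"] == 1.0

    def test_toy_table_matches_hand_computed_smoothed_counts(self):
        # 4 records, 2 features, smoothing 1; conditionals by hand:
        # class 0: f1 counts {0:2}, arity 2 -> P(f1=0|0) = (2+1)/(2+2) = 0.75
        table = RecordTable(
            pd.DataFrame(
                {"f1": [0, 0, 1, 1], "f2": [0, 1, 0, 1], "disease": [0, 0, 1, 1]}
            ),
            "disease",
        )
        model = nb_fit(table, smoothing=1.0)
        assert model.priors[0] == pytest.approx(0.5)
        assert model.conditionals["f1"][0][0] == pytest.approx(0.75)
        assert model.conditionals["f1"][0][1] == pytest.approx(0.25)
        assert model.conditionals["f1"][1][1] == pytest.approx(0.75)

    def test_conditionals_sum_to_one_per_class_and_feature(self):
        table, _ = synthetic_records(n=300, seed=0)
        model = nb_fit(table)
        for feat, per_class in model.conditionals.items():
            for cls, probs in per_class.items():
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_posteriors_normalized(self):
        table, _ = synthetic_records(n=200, seed=1)
        model = nb_fit(table)
        record = table.features.iloc[0]
        _, post = nb_predict(model, record)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_joint_enumeration_oracle_under_independence(self):
        # empirical distribution factorises exactly by construction, so the
        # naive factorisation must reproduce the exhaustive joint classifier
        # asymmetric priors keep every joint count distinct (no ties)
        priors = {0: 0.6, 1: 0.4}
        cond = {
            0: [(0.75, 0.25), (0.5, 0.5), (0.25, 0.75)],
            1: [(0.25, 0.75), (0.75, 0.25), (0.5, 0.5)],
        }
        rows = []
        N = 1600
        for cls in (0, 1):
            for vals in itertools.product((0, 1), repeat=3):
                p = priors[cls] * np.prod([cond[cls][k][v] for k, v in enumerate(vals)])
                count = round(N * p)
                rows.extend(
                    [{"f0": vals[0], "f1": vals[1], "f2": vals[2], "disease": cls}] * count
                )
        frame = pd.DataFrame(rows)
        table = RecordTable(frame, "disease")
        model = nb_fit(table, smoothing=0.0)

        # oracle: arg-max over empirical joint counts
        joint = frame.groupby(["f0", "f1", "f2", "disease"]).size()
        for vals in itertools.product((0, 1), repeat=3):
            record = {"f0": vals[0], "f1": vals[1], "f2": vals[2]}
            pred, _ = nb_predict(model, record)
            counts = {c: joint.get((*vals, c), 0) for c in (0, 1)}
            oracle = max(counts, key=counts.get)
            assert pred == oracle

    def test_symmetric_two_class_data_gives_half_half_posterior(self):
        frame = pd.DataFrame({"f": [0, 1, 0, 1], "disease": [0, 0, 1, 1]})
        model = nb_fit(RecordTable(frame, "disease"))
        _, post = nb_predict(model, {"f": 0})
        assert post[0] == pytest.approx(0.5)
        assert post[1] == pytest.approx(0.5)

    def test_parameter_recovery_on_synthetic_model(self):
        table, truth = synthetic_records(n=2000, n_informative=1, n_noise=3, seed=3)
        model = nb_fit(table)
        for feat, per_class in truth["conditionals"].items():
            for cls, probs in per_class.items():
                for val, p in probs.items():
                    assert model.conditionals[feat][cls][val] == pytest.approx(p, abs=0.05)


class TestBayesPosterior:
    def test_worked_example(self):
        post = bayes_posterior([0.9, 0.1], [0.5, 0.5])
        assert post == pytest.approx([0.9, 0.1])

    def test_equal_likelihoods_return_priors(self):
        post = bayes_posterior([0.3, 0.3, 0.3], [0.2, 0.5, 0.3])
        assert post == pytest.approx([0.2, 0.5, 0.3])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_output_sums_to_one(self, lik, pri):
        k = min(len(lik), len(pri))
        post = bayes_posterior(lik[:k], np.array(pri[:k]) / np.sum(pri[:k]))
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_joint_probability_chain_rule(self, p_cond, p_m):
        joint = joint_probability(p_cond, p_m)
        assert joint == pytest.approx(p_cond * p_m)
        assert 0.0 <= joint <= 1.0


class TestGeneticSelection:
    @pytest.fixture(scope="class")
    def ga_result(self):
        table, _ = synthetic_records(n=400, n_informative=1, n_noise=3, seed=5)
        cfg = GAConfig(population=16, generations=12)
        return table, ga_select_features(table, cfg, seed=5)

    def test_informative_feature_selected(self, ga_result):
        table, (best, _) = ga_result
        idx = table.feature_columns.index("inf_0")
        assert best.mask[idx]
        assert best.accuracy > 0.7

    def test_best_fitness_monotone_with_elitism(self, ga_result):
        _, (_, trace) = ga_result
        assert np.all(np.diff(trace) >= 0)

    def test_same_seed_same_mask(self, ga_result):
        table, (best, _) = ga_result
        again, _ = ga_select_features(table, GAConfig(population=16, generations=12), seed=5)
        assert np.array_equal(again.mask, best.mask)
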