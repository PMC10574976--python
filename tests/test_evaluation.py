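import math

import numpy as np
import pytest

import thermobrace as tb
from conftest import make_scores


def separable_records():
    """26 clear positives + 10 clear negatives."""
    pos = make_scores([0.001] * 26, [True] * 26, [1] * 26)
    neg = make_scores([0.9] * 10, [False] * 10, [0] * 10)
    return pos + neg


class TestBalancedSubsets:
    def test_study_shape_26_10(self):
        labels = [1] * 26 + [0] * 10
        subsets = tb.make_balanced_subsets(labels, n_subsets=10, per_class=10,
                                           seed=42)
        zeros = {i for i, y in enumerate(labels) if y == 0}
        assert len(subsets) == 10
        for s in subsets:
            assert len(s) == 20
            assert zeros <= set(s)                      # all minority included
            majority = [i for i in s if labels[i] == 1]
            assert len(majority) == len(set(majority))  # no repeats

    def test_exactly_balanced_dataset_gives_identical_subsets(self):
        labels = [1] * 10 + [0] * 10
        subsets = tb.make_balanced_subsets(labels, n_subsets=5, per_class=10,
                                           seed=0)
        assert all(sorted(s) == sorted(subsets[0]) for s in subsets)

    def test_too_few_minority_instances(self):
        with pytest.raises(ValueError, match="label-0"):
            tb.make_balanced_subsets([1] * 26 + [0] * 5, per_class=10, seed=0)

    def test_reproducible_and_seed_sensitive(self):
        labels = [1] * 26 + [0] * 10
        a = tb.make_balanced_subsets(labels, seed=1)
        b = tb.make_balanced_subsets(labels, seed=1)
        c = tb.make_balanced_subsets(labels, seed=2)
        assert a == b
        assert a != c


class TestLoocvAccuracy:
    def test_perfectly_separable_records(self):
        recs = (make_scores([0.001] * 10, [True] * 10, [1] * 10)
                + make_scores([0.9] * 10, [False] * 10, [0] * 10))
        acc, outcomes = tb.loocv_accuracy(recs)
        assert acc == 100.0
        assert outcomes == [1] * 20

    def test_identical_records_constant_zero_classifier(self):
        # p above the grid maximum: the classifier predicts 0 everywhere,
        # so exactly the 10 negative folds are correct
        recs = make_scores([0.6] * 20, [True] * 20, [1] * 10 + [0] * 10)
        acc, _ = tb.loocv_accuracy(recs)
        assert acc == 50.0

    def test_identical_in_grid_records_hit_loocv_pathology(self):
        # identical records with p inside the grid: on every fold the
        # training majority is the opposite class of the held-out record,
        # so the trained constant classifier gets every fold wrong
        recs = make_scores([0.2] * 20, [True] * 20, [1] * 10 + [0] * 10)
        acc, _ = tb.loocv_accuracy(recs)
        assert acc == 0.0

    def test_accuracy_granularity_for_20_records(self):
        rng = np.random.default_rng(0)
        recs = make_scores(rng.uniform(0, 1, 20), rng.random(20) > 0.5,
                           [1] * 10 + [0] * 10)
        acc, outcomes = tb.loocv_accuracy(recs)
        assert acc % 5.0 == 0.0
        assert len(outcomes) == 20

    def test_invariant_to_grid_value_duplication(self):
        rng = np.random.default_rng(3)
        recs = make_scores(rng.uniform(0, 0.6, 20), rng.random(20) > 0.3,
                           list(rng.integers(0, 2, 20)))
        grid = tb.ThresholdGrid(0.005, 0.5, 50).values
        dup = np.sort(np.concatenate([grid, grid, grid]))
        assert tb.loocv_accuracy(recs, grid) == tb.loocv_accuracy(recs, dup)

    def test_smallest_maximizer_tie_break(self):
        # one positive with tiny p, rest negatives: any threshold below 0.9
        # is equally good on training folds containing the positive, and the
        # smallest one must be chosen -> held-out negatives stay correct
        recs = (make_scores([1e-4], [True], [1])
                + make_scores([0.9] * 9, [True] * 9, [0] * 9))
        acc, _ = tb.loocv_accuracy(recs)
        assert acc == 100.0


class TestTypeAUncertainty:
    @pytest.mark.parametrize("correct,expected_1dp", [
        (14, 10.5),  # printed set #1
        (15, 9.9),   # printed set #4
        (20, 0.0),
    ])
    def test_20_fold_values(self, correct, expected_1dp):
        outcomes = [1] * correct + [0] * (20 - correct)
        assert round(tb.type_a_uncertainty(outcomes), 1) == expected_1dp

    def test_closed_form_sweep(self):
        """u equals 100*sqrt(phat(1-phat)/(n-1)) for every n <= 50."""
        for n in range(2, 51):
            for k in range(0, n + 1):
                u = tb.type_a_uncertainty([1] * k + [0] * (n - k))
                phat = k / n
                closed = 100.0 * math.sqrt(phat * (1 - phat) / (n - 1))
                assert abs(u - closed) <= 1e-12

    def test_single_outcome_rejected(self):
        with pytest.raises(ValueError):
            tb.type_a_uncertainty([1])


class TestAggregation:
    U_ROW = [10.5, 11.4, 10.9, 9.9, 10.9, 10.5, 11.2, 10.9, 10.9, 10.9]

    def test_propagated_mean_uncertainty_from_printed_row(self):
        assert round(tb.propagate_mean_uncertainty(self.U_ROW), 1) == 3.4

    def test_equal_values_closed_form(self):
        assert tb.propagate_mean_uncertainty([2.0] * 16) == pytest.approx(0.5)

    def test_single_value_passthrough(self):
        assert tb.propagate_mean_uncertainty([1.7]) == pytest.approx(1.7)

    @pytest.mark.parametrize("u,k,expected", [(3.4, 2, 6.8), (0.0, 2, 0.0),
                                              (1.5, 3, 4.5)])
    def test_expanded_uncertainty(self, u, k, expected):
        assert tb.expanded_uncertainty(u, k) == pytest.approx(expected)


class TestEvaluateSystem:
    def test_separable_limit(self):
        report = tb.evaluate_system(separable_records(), seed=0)
        assert report.mean_accuracy_pct == 100.0
        assert report.u_mean_pct == 0.0
        assert report.expanded_u_pct == 0.0

    def test_same_seed_reproduces_report(self):
        rng = np.random.default_rng(8)
        recs = make_scores(rng.uniform(0, 1, 36), rng.random(36) > 0.4,
                           [1] * 26 + [0] * 10)
        assert tb.evaluate_system(recs, seed=5) == tb.evaluate_system(recs, seed=5)

    def test_report_internal_consistency(self):
        rng = np.random.default_rng(9)
        recs = make_scores(rng.uniform(0, 1, 36), rng.random(36) > 0.4,
                           [1] * 26 + [0] * 10)
        rep = tb.evaluate_system(recs, seed=3, coverage_k=2.0)
        assert rep.mean_accuracy_pct == pytest.approx(
            np.mean([s.accuracy_pct for s in rep.per_subset]))
        assert rep.expanded_u_pct == pytest.approx(2.0 * rep.u_mean_pct)
        for s in rep.per_subset:
            assert s.accuracy_pct == pytest.approx(
                100.0 * np.mean(s.fold_outcomes))

    def test_summary_table_rounds_to_one_decimal(self):
        rep = tb.evaluate_system(separable_records(), seed=0)
        table = rep.summary_table()
        assert "100.0" in table and "0.0" in table


class TestScoreIO:
    def test_round_trip(self, tmp_path):
        recs = separable_records()
        path = str(tmp_path / "scores.csv")
        tb.write_scores(recs, path)
        assert tb.read_scores(path) == recs

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("p_value,label\n0.1,1\n")
        with pytest.raises(ValueError, match="direction_ok"):
            tb.read_scores(str(path))
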