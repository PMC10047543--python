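"""Weighted-MSE scoring, paired bootstraps and significance rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beatpd.challenge_scoring as cs


def truth_frame(subject_sizes: dict, labels=None, rng=None):
    rows = []
    for s, n in subject_sizes.items():
        for i in range(n):
            label = labels[s][i] if labels else (
                float(rng.integers(0, 5)) if rng else float(i % 5))
            rows.append((f"{s}-{i:04d}", s, label))
    return pd.DataFrame(rows, columns=["measurement_id", "subject_id",
                                       "label"])


def brute_force_wmse(per_subject):
    """Oracle with explicit loops over the scoring definition."""
    num = den = 0.0
    for n, mse in per_subject:
        w = n ** 0.5
        num += w * mse
        den += w
    return num / den


class TestPointScores:
    def test_perfect_predictions_score_zero(self):
        truth = truth_frame({"A": 5})
        pred = dict(zip(truth["measurement_id"], truth["label"]))
        assert cs.subject_mse(pred, truth, "A") == 0.0

    def test_unit_offset_gives_unit_mse(self):
        truth = truth_frame({"A": 4})
        pred = {m: v + 1 for m, v in zip(truth["measurement_id"],
                                         truth["label"])}
        assert cs.subject_mse(pred, truth, "A") == 1.0

    def test_two_point_example(self):
        truth = truth_frame({"A": 2}, labels={"A": [0.0, 2.0]})
        pred = {m: 1.0 for m in truth["measurement_id"]}
        assert cs.subject_mse(pred, truth, "A") == 1.0

    def test_missing_prediction_is_an_error(self):
        truth = truth_frame({"A": 3})
        pred = {m: 0.0 for m in truth["measurement_id"][:-1]}
        with pytest.raises(cs.ScoringError, match="[Mm]issing"):
            cs.score_predictions(pred, truth)

    def test_weights_cancel_when_all_mses_equal(self):
        table = cs.ScoreTable(pd.DataFrame(
            {"subject_id": list("ABC"), "n": [5, 50, 11],
             "mse": [0.3, 0.3, 0.3]}))
        assert cs.weighted_mse(table) == pytest.approx(0.3)

    def test_hand_computed_weighting_99_11(self):
        # sqrt(99)/sqrt(11) = 3, so WMSE = (3*1 + 1*0)/4
        table = cs.ScoreTable(pd.DataFrame(
            {"subject_id": ["A", "B"], "n": [99, 11], "mse": [1.0, 0.0]}))
        assert cs.weighted_mse(table) == pytest.approx(0.75)

    def test_single_subject_wmse_is_its_mse(self):
        table = cs.ScoreTable(pd.DataFrame(
            {"subject_id": ["A"], "n": [7], "mse": [0.42]}))
        assert cs.weighted_mse(table) == pytest.approx(0.42)

    def test_empty_table_raises(self):
        with pytest.raises(cs.ScoringError):
            cs.weighted_mse(cs.ScoreTable(pd.DataFrame(
                columns=["subject_id", "n", "mse"])))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 99),
                              st.floats(0, 10, allow_nan=False)),
                    min_size=1, max_size=20))
    def test_wmse_matches_brute_force_and_bounds(self, rows):
        table = cs.ScoreTable(pd.DataFrame(
            [(f"S{i}", n, m) for i, (n, m) in enumerate(rows)],
            columns=["subject_id", "n", "mse"]))
        got = cs.weighted_mse(table)
        assert got == pytest.approx(brute_force_wmse(rows), abs=1e-12)
        mses = [m for _, m in rows]
        assert min(mses) - 1e-12 <= got <= max(mses) + 1e-12

    def test_scale_equivariance_of_errors(self, rng):
        truth = truth_frame({"A": 10, "B": 7}, rng=rng)
        eps = {m: rng.normal() for m in truth["measurement_id"]}
        for c in (1.0, 2.5):
            pred = {m: t + c * eps[m]
                    for m, t in zip(truth["measurement_id"], truth["label"])}
            table = cs.score_predictions(pred, truth)
            if c == 1.0:
                base = cs.weighted_mse(table)
            else:
                assert cs.weighted_mse(table) == pytest.approx(c ** 2 * base)


class TestBootstrap:
    def make_sets(self, rng, sizes={"A": 12, "B": 20}):
        truth = truth_frame(sizes, rng=rng)
        null = {m: 2.0 for m in truth["measurement_id"]}
        good = {m: t + rng.normal(0, 0.3)
                for m, t in zip(truth["measurement_id"], truth["label"])}
        return truth, {"Null": null, "good": good}

    def test_paired_identical_sets_have_identical_iterations(self, rng):
        truth, sets = self.make_sets(rng)
        sets["copy"] = dict(sets["good"])
        res = cs.bootstrap_scores(sets, truth, B=50, seed=4)
        assert np.array_equal(res.scores["good"], res.scores["copy"])

    def test_singleton_subjects_make_resampling_the_identity(self, rng):
        truth = truth_frame({"A": 1, "B": 1, "C": 1}, rng=rng)
        pred = {m: 0.0 for m in truth["measurement_id"]}
        res = cs.bootstrap_scores({"m": pred}, truth, B=1, seed=0)
        assert res.scores["m"].iloc[0] == pytest.approx(res.point_wmse["m"])

    def test_bootstrap_mean_near_point_estimate(self, rng):
        truth, sets = self.make_sets(rng, sizes={"A": 40, "B": 40})
        res = cs.bootstrap_scores(sets, truth, B=400, seed=5)
        for m in sets:
            se = res.scores[m].std()
            assert abs(res.scores[m].mean()
                       - res.point_wmse[m]) < 3 * se / np.sqrt(1) + 1e-9

    def test_b_below_one_raises(self, rng):
        truth, sets = self.make_sets(rng)
        with pytest.raises(cs.ScoringError):
            cs.bootstrap_scores(sets, truth, B=0)

    def test_determinism_under_seed(self, rng):
        truth, sets = self.make_sets(rng)
        a = cs.bootstrap_scores(sets, truth, B=30, seed=9).scores
        b = cs.bootstrap_scores(sets, truth, B=30, seed=9).scores
        pd.testing.assert_frame_equal(a, b)


class TestPValues:
    def boot(self, rng, extra=None):
        truth = truth_frame({"A": 15, "B": 25}, rng=rng)
        null = {m: 2.0 for m in truth["measurement_id"]}
        sets = {"Null": null, "same": dict(null)}
        if extra:
            sets.update(extra(truth))
        return cs.bootstrap_scores(sets, truth, B=200, seed=1)

    def test_null_identical_submission_gets_half(self, rng):
        res = self.boot(rng)
        assert cs.pvalue_vs_null(res, "same") == 0.5

    def test_strictly_better_model_gets_zero(self, rng):
        res = self.boot(rng, extra=lambda truth: {
            "perfect": dict(zip(truth["measurement_id"], truth["label"]))})
        assert cs.pvalue_vs_null(res, "perfect") == 0.0

    def test_strict_tie_rule_is_available(self, rng):
        res = self.boot(rng)
        assert cs.pvalue_vs_null(res, "same", ties="strict") == 0.0

    def test_absent_model_raises(self, rng):
        with pytest.raises(cs.ScoringError):
            cs.pvalue_vs_null(self.boot(rng), "ghost")


class TestDistinguishability:
    def test_uniformly_better_model_is_distinguishable(self):
        scores = pd.DataFrame({"A": np.linspace(0.1, 0.2, 1000),
                               "B": np.linspace(0.3, 0.4, 1000)})
        res = cs.BootstrapResult(scores, {}, 1000, 0)
        assert cs.distinguishability(res, "A", "B") < 1e-6

    def test_identical_models_give_p_one(self):
        scores = pd.DataFrame({"A": np.ones(100), "B": np.ones(100)})
        res = cs.BootstrapResult(scores, {}, 100, 0)
        assert cs.distinguishability(res, "A", "B") == 1.0

    def test_symmetric_noise_differences_are_indistinguishable(self, rng):
        a = rng.normal(0.5, 0.05, 1000)
        res = cs.BootstrapResult(
            pd.DataFrame({"A": a, "B": a + rng.normal(0, 0.01, 1000)}),
            {}, 1000, 0)
        assert 0.05 < cs.distinguishability(res, "A", "B") < 0.95


class TestLeaderboard:
    def test_null_alone_has_undefined_p(self, rng):
        truth = truth_frame({"A": 10}, rng=rng)
        null = {m: 1.0 for m in truth["measurement_id"]}
        board = cs.leaderboard({"Null": null}, truth, B=20, seed=0)
        assert len(board) == 1 and np.isnan(board["p_vs_null"].iloc[0])

    def test_ranks_ascend_by_wmse_with_lexicographic_ties(self, rng):
        truth = truth_frame({"A": 10, "B": 12}, rng=rng)
        perfect = dict(zip(truth["measurement_id"], truth["label"]))
        null = {m: 2.0 for m in truth["measurement_id"]}
        board = cs.leaderboard(
            {"Null": null, "zeta": perfect, "alpha": dict(perfect)},
            truth, B=50, seed=2)
        assert list(board["submission_id"][:2]) == ["alpha", "zeta"]
        assert list(board["rank"]) == [1, 2, 3]
        assert board["significant_vs_null"][:2].all()
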