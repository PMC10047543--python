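"""Nested-CV fold plan, aggregation, stacking, CES and subset search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

import beatpd.ensemble_builder as eb


def make_matrix(rng, n_per_subject=30, subjects=("A", "B"), bases=None,
                truth_fn=None, with_folds=True):
    bases = bases or {"b1": 0.3, "b2": 0.6, "b3": 1.0}
    rows = []
    for s in subjects:
        for i in range(n_per_subject):
            truth = truth_fn(rng) if truth_fn else float(rng.integers(0, 5))
            row = {"measurement_id": f"{s}-{i:04d}", "subject_id": s,
                   "truth": truth}
            for name, sd in bases.items():
                row[name] = truth + rng.normal(0, sd)
            rows.append(row)
    frame = pd.DataFrame(rows)
    if with_folds:
        frame["fold"] = np.arange(len(frame)) % 5
    return eb.matrix_from_frame(frame)


class TestNestedCv:
    def obs(self, n=60, subjects=("A",)):
        rows = [{"measurement_id": f"{s}-{i:04d}", "subject_id": s,
                 "label": float(i % 3)}
                for s in subjects for i in range(n)]
        return pd.DataFrame(rows)

    def test_sixty_observations_give_folds_of_ten(self):
        folds = eb.nested_cv(self.obs(60), k=6, seed=0)
        assert folds.value_counts().to_dict() == {f: 10 for f in range(6)}

    def test_folds_partition_the_observations(self):
        obs = self.obs(31, subjects=("A", "B"))
        folds = eb.nested_cv(obs, k=6, seed=1)
        assert len(folds) == len(obs)
        assert not folds.index.duplicated().any()

    def test_same_seed_same_plan(self):
        a = eb.nested_cv(self.obs(45), k=6, seed=3)
        b = eb.nested_cv(self.obs(45), k=6, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_observations_suggests_reducing_k(self):
        with pytest.raises(ValueError, match="reduce k"):
            eb.nested_cv(self.obs(4), k=6)


class TestUnsupervised:
    def test_identical_columns_are_a_fixed_point(self, rng):
        m = make_matrix(rng, bases={"b1": 0.0, "b2": 0.0})
        for how in ("mean", "median"):
            assert np.allclose(eb.aggregate_unsupervised(m, how),
                               m.frame["b1"])

    def test_row_example_median_and_mean(self):
        frame = pd.DataFrame({"measurement_id": ["m"], "subject_id": ["A"],
                              "truth": [1.0], "b1": [0.0], "b2": [1.0],
                              "b3": [5.0]})
        m = eb.matrix_from_frame(frame)
        assert eb.aggregate_unsupervised(m, "median").iloc[0] == 1.0
        assert eb.aggregate_unsupervised(m, "mean").iloc[0] == 2.0

    def test_single_base_is_identity(self, rng):
        m = make_matrix(rng, bases={"only": 0.5})
        assert np.allclose(eb.aggregate_unsupervised(m, "mean"),
                           m.frame["only"])

    def test_permutation_invariance_in_base_order(self, rng):
        m = make_matrix(rng)
        reordered = eb.BasePredictionMatrix(m.frame, ["b3", "b1", "b2"])
        for how in ("mean", "median"):
            assert np.allclose(eb.aggregate_unsupervised(m, how),
                               eb.aggregate_unsupervised(reordered, how))

    def test_median_robust_to_one_corrupted_base(self, rng):
        m = make_matrix(rng, bases={"b1": 0.0, "b2": 0.0, "b3": 0.0})
        corrupted = m.frame.copy()
        corrupted["b3"] = 1e9
        med = eb.aggregate_unsupervised(eb.matrix_from_frame(corrupted),
                                        "median")
        assert np.allclose(med, m.frame["b1"])


class TestStacking:
    def test_truth_equal_to_one_base_concentrates_weight(self, rng):
        m = make_matrix(rng, n_per_subject=60,
                        bases={"exact": 1e-6, "noisy": 1.0, "junk": 2.0})
        model = eb.StackingEnsemble("ridge", "raw", seed=0).fit(m)
        weights = dict(zip(m.base_names, model.model_.coef_))
        assert weights["exact"] > 0.8
        pred = model.predict(m).to_numpy()
        mse = float(((pred - m.frame["truth"].to_numpy()) ** 2).mean())
        for other in ("noisy", "junk"):
            base_mse = float(((m.frame[other] - m.frame["truth"]) ** 2).mean())
            assert mse < base_mse

    def test_z_score_variant_invariant_to_affine_base_rescaling(self, rng):
        m = make_matrix(rng, n_per_subject=50)
        model = eb.StackingEnsemble("ridge", "z_scored", seed=0).fit(m)
        rescaled = m.frame.copy()
        rescaled["b1"] = 10.0 * rescaled["b1"] + 3.0
        m2 = eb.matrix_from_frame(rescaled)
        model2 = eb.StackingEnsemble("ridge", "z_scored", seed=0).fit(m2)
        assert np.allclose(model.predict(m), model2.predict(m2), atol=1e-8)

    def test_single_base_stacking_recalibrates_monotonically(self, rng):
        m = make_matrix(rng, n_per_subject=80, bases={"only": 0.4})
        model = eb.StackingEnsemble("linear", "raw", seed=0).fit(m)
        pred = model.predict(m).to_numpy()
        mse = float(((pred - m.frame["truth"].to_numpy()) ** 2).mean())
        identity_mse = float(((m.frame["only"] - m.frame["truth"]) ** 2)
                             .mean())
        assert mse <= identity_mse + 1e-9

    def test_per_subject_variant_falls_back_for_small_subjects(self, rng):
        frame = make_matrix(rng, n_per_subject=30, subjects=("A",)).frame
        tiny = make_matrix(rng, n_per_subject=4, subjects=("B",)).frame
        m = eb.matrix_from_frame(pd.concat([frame, tiny], ignore_index=True))
        model = eb.StackingEnsemble("ridge", "per_subject", seed=0).fit(m)
        assert "A" in model.subject_models_
        assert "B" not in model.subject_models_
        assert len(model.predict(m)) == len(m.frame)

    def test_complementary_bases_are_combined(self, rng):
        # two bases each carry an independent half of the signal
        rows = []
        for i in range(200):
            u, v = rng.normal(size=2)
            rows.append({"measurement_id": f"m{i:04d}", "subject_id": "A",
                         "truth": u + v, "half_u": u + rng.normal(0, 0.05),
                         "half_v": v + rng.normal(0, 0.05)})
        frame = pd.DataFrame(rows)
        frame["fold"] = np.arange(len(frame)) % 5
        m = eb.matrix_from_frame(frame)
        model = eb.StackingEnsemble("linear", "raw", seed=0).fit(m)
        mse = float(((model.predict(m).to_numpy()
                      - m.frame["truth"].to_numpy()) ** 2).mean())
        for b in ("half_u", "half_v"):
            assert mse < float(((m.frame[b] - m.frame["truth"]) ** 2).mean())


class TestCes:
    def test_single_base_selects_it(self, rng):
        m = make_matrix(rng, bases={"only": 0.5})
        assert eb.ces_select(m).members_ == ["only"]

    def test_informative_base_wins_over_noise(self, rng):
        m = make_matrix(rng, n_per_subject=60,
                        bases={"good": 0.1, "noise1": 3.0, "noise2": 3.0})
        members = set(eb.ces_select(m).members_)
        assert members == {"good"}

    def test_greedy_guarantee_not_worse_than_best_single_base(self, rng):
        m = make_matrix(rng, n_per_subject=50)
        model = eb.ces_select(m)
        ens_wmse = m.wmse_of(model.predict(m).to_numpy())
        best_single = min(m.wmse_of(m.frame[b].to_numpy())
                          for b in m.base_names)
        assert ens_wmse <= best_single + 1e-12


class TestSubsetLinear:
    def test_five_bases_enumerate_31_subsets(self, rng):
        m = make_matrix(rng, n_per_subject=40,
                        bases={f"b{i}": 0.5 for i in range(5)})
        model = eb.subset_linear_select(m, seed=0)
        assert model.n_subsets_evaluated_ == 31

    def test_truth_equals_base_recovers_it(self, rng):
        m = make_matrix(rng, n_per_subject=60,
                        bases={"exact": 1e-9, "junk1": 2.0, "junk2": 2.0})
        model = eb.subset_linear_select(m, seed=0)
        assert "exact" in model.subset_
        pred = model.predict(m).to_numpy()
        assert float(((pred - m.frame["truth"].to_numpy()) ** 2).mean()) < 1e-3

    def test_matches_independent_exhaustive_enumeration(self, rng):
        m = make_matrix(rng, n_per_subject=30,
                        bases={"b1": 0.2, "b2": 0.7, "b3": 1.5})
        model = eb.SubsetLinearEnsemble(seed=4).fit(m)
        # independent brute force over the same split and alpha grid
        learn = model._split(m)
        X = m.X()
        y = m.frame["truth"].to_numpy()
        hold = m.subset(~learn)
        best = (np.inf, None, None)
        names = m.base_names
        for r in range(1, 4):
            for combo in itertools.combinations(range(3), r):
                for alpha in eb.DEFAULT_ALPHA_GRID:
                    reg = Ridge(alpha=alpha)
                    reg.fit(X[np.ix_(learn, combo)], y[learn])
                    s = hold.wmse_of(reg.predict(X[np.ix_(~learn, combo)]))
                    if s < best[0]:
                        best = (s, tuple(names[i] for i in combo), alpha)
        assert model.subset_ == best[1] and model.alpha_ == best[2]

    def test_more_than_twelve_bases_refused(self, rng):
        m = make_matrix(rng, n_per_subject=20,
                        bases={f"b{i:02d}": 0.5 for i in range(13)})
        with pytest.raises(ValueError, match="CES or stacking"):
            eb.subset_linear_select(m)


class TestSelectAndFinalize:
    def matrices(self, rng):
        inner = make_matrix(rng, n_per_subject=40)
        eval_m = make_matrix(rng, n_per_subject=10)
        full = make_matrix(rng, n_per_subject=50)
        test = make_matrix(rng, n_per_subject=15)
        return inner, eval_m, full, test

    def test_argmin_selection_within_each_class(self, rng):
        inner, eval_m, full, test = self.matrices(rng)
        final = eb.select_and_finalize(inner, eval_m, full, test, seed=0)
        unsup = {n: final.eval_wmse[n] for n in eb.UNSUPERVISED}
        assert final.unsupervised_name == min(unsup, key=unsup.get)
        sup = {n: w for n, w in final.eval_wmse.items()
               if n not in eb.UNSUPERVISED}
        assert final.eval_wmse[final.supervised_name] == min(sup.values())
        assert set(final.test_predictions) == {"unsupervised", "supervised"}

    def test_evaluation_truth_never_reaches_fitting(self, rng):
        inner, eval_m, full, test = self.matrices(rng)
        poisoned = eval_m.frame.copy()
        poisoned["truth"] = 1e6
        a = eb.StackingEnsemble("ridge", "raw", seed=0).fit(inner)
        b = eb.StackingEnsemble("ridge", "raw", seed=0).fit(inner)
        # same inner fit regardless of what the evaluation fold contains
        assert np.allclose(a.predict(eb.matrix_from_frame(poisoned)),
                           b.predict(eval_m))
        c = eb.ces_select(inner)
        assert c.members_ == eb.ces_select(inner).members_
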