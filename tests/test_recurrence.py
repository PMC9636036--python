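"""Monte Carlo CV machinery: splits, AUC/kappa, ranking, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

import methylstate as ms
from methylstate.recurrence import ClinicalTable


def _clinical(y, n=None, rng=None, index=None):
    n = n or len(y)
    rng = rng or np.random.default_rng(0)
    idx = pd.Index(index) if index is not None else pd.Index([f"p{i}" for i in range(n)])
    return ClinicalTable(pd.DataFrame({
        "recurrence": np.asarray(y, dtype=int),
        "tnm_stage": rng.integers(1, 5, n),
        "metastasis": rng.integers(0, 2, n),
        "msi": rng.integers(0, 2, n),
    }, index=idx))


class TestEnumerateCombinations:
    @pytest.mark.parametrize("k,expected", [(10, 1023), (2, 3), (1, 1)])
    def test_counts(self, k, expected):
        labels = [f"c{i}" for i in range(k)]
        assert len(ms.enumerate_combinations(labels)) == expected

    def test_order_by_size_then_lexicographic(self):
        out = ms.enumerate_combinations(["b", "a", "c"])
        assert out[:3] == [("a",), ("b",), ("c",)]
        assert out[3] == ("a", "b")

    def test_guard_against_explosion(self):
        with pytest.raises(ValueError, match="16"):
            ms.enumerate_combinations([f"c{i}" for i in range(17)])

    def test_size_restriction(self):
        out = ms.enumerate_combinations([f"c{i}" for i in range(10)], sizes=[3])
        assert len(out) == 120
        assert all(len(c) == 3 for c in out)


class TestMonteCarloSplits:
    def test_sizes_and_stratification(self):
        y = np.array([0] * 5 + [1] * 5)
        splits = ms.monte_carlo_splits(10, y, n_repeats=20, seed=1)
        assert len(splits) == 20
        for tr, te in splits:
            assert len(tr) == 7 and len(te) == 3
            assert len(np.intersect1d(tr, te)) == 0
            assert set(y[tr]) == {0, 1}
            assert set(y[te]) == {0, 1}

    def test_exactly_n_distinct_seeded_splits(self):
        y = np.array([0] * 40 + [1] * 30)
        splits = ms.monte_carlo_splits(70, y, n_repeats=100, seed=3)
        assert len(splits) == 100
        keys = {tuple(tr) for tr, _ in splits}
        assert len(keys) > 95  # seeded draws, essentially all distinct
        again = ms.monte_carlo_splits(70, y, n_repeats=100, seed=3)
        assert all(np.array_equal(a[0], b[0]) for a, b in zip(splits, again))

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ms.monte_carlo_splits(10, np.ones(10), n_repeats=5)

    def test_stratified_proportion_preserved(self):
        y = np.array([0] * 80 + [1] * 20)
        for tr, te in ms.monte_carlo_splits(100, y, n_repeats=10, seed=0):
            assert y[tr].sum() == 14  # 0.7 * 20 positives


class TestMetrics:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((0.1, 0.2, 0.8, 0.9), (0, 0, 1, 1), 1.0),
            # positives {0.2, 0.9} vs negatives {0.1, 0.8}: 3 of 4 pairs ranked
            ((0.1, 0.8, 0.2, 0.9), (0, 0, 1, 1), 0.75),
            ((0.5, 0.5, 0.5, 0.5), (0, 1, 0, 1), 0.5),
        ],
    )
    def test_auc_rank_small_cases(self, scores, labels, expected):
        assert ms.auc_rank(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_auc_matches_trapezoidal_roc(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if len(set(y)) < 2:
                continue
            s = rng.random(30).round(1)  # coarse scores force ties
            assert ms.auc_rank(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_kappa_hand_computed_confusion(self):
        # confusion [[20,5],[10,15]]: po=0.7, pe=0.5 -> kappa 0.4
        truth = np.array([0] * 25 + [1] * 25)
        pred = np.array([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        assert ms.cohen_kappa(pred, truth) == pytest.approx(0.4)

    def test_kappa_matches_sklearn(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, 40)
            b = rng.integers(0, 2, 40)
            if len(set(a)) < 2 and len(set(b)) < 2 and a[0] == b[0]:
                continue
            assert ms.cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )


class TestTrainEval:
    def _informative(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        props = pd.DataFrame(
            rng.dirichlet(np.ones(4), n), columns=list("abcd"),
            index=[f"p{i}" for i in range(n)],
        )
        logit = 8 * props["a"] - 8 * props["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return props, _clinical(y, rng=rng)

    def test_informative_features_beat_chance(self):
        props, clinical = self._informative()
        splits = ms.monte_carlo_splits(len(props), clinical.recurrence,
                                       n_repeats=20, seed=0)
        res = ms.train_eval_combination(props, clinical, ("a", "b"), splits)
        assert np.nanmean(res["auc"]) > 0.65
        assert res["auc"].shape == (20,)
        assert res["kappa"].shape == (20,)

    def test_model_kinds_agree_on_strong_signal(self):
        props, clinical = self._informative()
        splits = ms.monte_carlo_splits(len(props), clinical.recurrence,
                                       n_repeats=10, seed=1)
        means = {}
        for kind in ("extra_trees", "extra_trees_sklearn", "random_forest"):
            res = ms.train_eval_combination(props, clinical, ("a", "b"), splits,
                                            model_kind=kind)
            means[kind] = np.nanmean(res["auc"])
        assert max(means.values()) - min(means.values()) < 0.07

    def test_clinical_fields_are_usable_features(self):
        rng = np.random.default_rng(5)
        n = 150
        props = pd.DataFrame(rng.dirichlet(np.ones(3), n), columns=list("abc"),
                             index=[f"p{i}" for i in range(n)])
        tnm = rng.integers(1, 5, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(tnm - 2.5) * 1.5))).astype(int)
        clinical = ClinicalTable(pd.DataFrame(
            {"recurrence": y, "tnm_stage": tnm,
             "metastasis": rng.integers(0, 2, n), "msi": rng.integers(0, 2, n)},
            index=props.index))
        splits = ms.monte_carlo_splits(n, y, n_repeats=20, seed=2)
        with_tnm = ms.train_eval_combination(
            props, clinical, ("a",), splits, clinical_fields=("tnm_stage",))
        without = ms.train_eval_combination(props, clinical, ("a",), splits)
        assert np.nanmean(with_tnm["auc"]) > np.nanmean(without["auc"]) + 0.1


class TestClinicalIntegration:
    def test_informative_clinical_subset_tops_the_sweep(self):
        rng = np.random.default_rng(21)
        n = 160
        props = pd.DataFrame(rng.dirichlet(np.ones(3), n), columns=list("abc"),
                             index=[f"p{i}" for i in range(n)])
        tnm = rng.integers(1, 5, n)
        logit = 6 * props["a"] - 6 * props["b"] + 1.2 * (tnm - 2.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        clinical = ClinicalTable(pd.DataFrame(
            {"recurrence": y, "tnm_stage": tnm,
             "metastasis": rng.integers(0, 2, n), "msi": rng.integers(0, 2, n)},
            index=props.index))
        splits = ms.monte_carlo_splits(n, y, n_repeats=20, seed=4)
        sweep = ms.clinical_combination_search(props, clinical, ("a", "b"), splits)
        assert len(sweep) == 8  # all subsets of the three clinical fields
        assert "tnm_stage" in sweep.iloc[0]["clinical_fields"]
        none_auc = sweep.loc[sweep["clinical_fields"].map(len) == 0, "mean_auc"].iloc[0]
        # informative covariates never cost more than split noise
        assert sweep.iloc[0]["mean_auc"] >= none_auc - 0.02


class TestRanking:
    def test_rank_by_mean_auc_then_size(self):
        auc = {
            ("a",): np.array([0.69, 0.69]),
            ("b", "c"): np.array([0.55, 0.55]),
            ("a", "b", "c"): np.array([0.69, 0.69]),
        }
        kappa = {k: np.zeros(2) for k in auc}
        report = ms.rank_combinations(auc, kappa, n_repeats=2)
        order = list(report.ranking["combination"])
        assert order[0] == ("a",)  # tie with the 3-subset broken by size
        assert order[-1] == ("b", "c")


class TestCompareApproaches:
    def test_identical_distributions_p_near_one(self):
        a = np.linspace(0.4, 0.8, 30)
        assert ms.compare_approaches(a, a) > 0.9

    def test_fully_separated_distributions(self):
        p = ms.compare_approaches([0.9] * 50, [0.5] * 50)
        assert p < 1e-10
        u = stats.mannwhitneyu([0.9] * 50, [0.5] * 50, alternative="two-sided")
        assert p == pytest.approx(u.pvalue)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            ms.compare_approaches([0.5] * 3, [0.6] * 3)


class TestPermutationImportance:
    def test_dominant_feature_floors_at_one_over_nplus1(self):
        rng = np.random.default_rng(0)
        n = 80
        x = rng.normal(size=n)
        y = (x > 0).astype(int)  # feature 0 separates perfectly
        feats = pd.DataFrame({"signal": x, "noise1": rng.normal(size=n),
                              "noise2": rng.normal(size=n)})
        res = ms.permutation_feature_importance(feats, y, n_perms=100, seed=1)
        assert res.loc["signal", "p_value"] == pytest.approx(1 / 101)

    def test_noise_feature_p_not_small(self):
        rng = np.random.default_rng(2)
        n = 60
        y = rng.integers(0, 2, n)
        feats = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"))
        res = ms.permutation_feature_importance(feats, y, n_perms=50, seed=3)
        assert (res["p_value"] > 0.01).all()

    def test_zero_permutations_rejected(self):
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="n_perms"):
            ms.permutation_feature_importance(feats, np.tile([0, 1], 10), n_perms=0)


class TestCrossCohort:
    def _cohort(self, seed, n=200):
        rng = np.random.default_rng(seed)
        props = pd.DataFrame(rng.dirichlet(np.ones(4), n), columns=list("abcd"),
                             index=[f"s{seed}_{i}" for i in range(n)])
        logit = 10 * props["a"] - 10 * props["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return props, _clinical(y, rng=rng, index=props.index)

    def test_transfer_close_to_within_cohort(self):
        ptr, ctr = self._cohort(1)
        pte, cte = self._cohort(2)
        transfer = ms.cross_cohort_predict(ptr, ctr, pte, cte, ("a", "b"),
                                           n_repeats=10)
        splits = ms.monte_carlo_splits(len(ptr), ctr.recurrence, n_repeats=20, seed=0)
        within = ms.train_eval_combination(ptr, ctr, ("a", "b"), splits)
        assert abs(np.mean(transfer["auc"]) - np.nanmean(within["auc"])) < 0.1

    def test_permuted_test_labels_give_chance_auc(self):
        # average over several fresh permutations: a single fixed permutation
        # keeps a chance-level cohort association of order 1/sqrt(n)
        ptr, ctr = self._cohort(3)
        pte, cte = self._cohort(4)
        rng = np.random.default_rng(9)
        means = []
        for _ in range(8):
            t = cte.table.copy()
            t["recurrence"] = rng.permutation(t["recurrence"].to_numpy())
            res = ms.cross_cohort_predict(ptr, ctr, pte, ClinicalTable(t),
                                          ("a", "b"), n_repeats=3)
            means.append(np.mean(res["auc"]))
        assert abs(np.mean(means) - 0.5) < 0.06

    def test_feature_mismatch_detected(self):
        ptr, ctr = self._cohort(5)
        pte, cte = self._cohort(6)
        with pytest.raises(ValueError, match="absent"):
            ms.cross_cohort_predict(ptr, ctr, pte.drop(columns="b"), cte, ("a", "b"))


class TestClinicalTable:
    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="recurrence"):
            ClinicalTable(pd.DataFrame({"recurrence": [0, 2]}))

    def test_invalid_tnm_rejected(self):
        with pytest.raises(ValueError, match="tnm"):
            ClinicalTable(pd.DataFrame({"recurrence": [0, 1], "tnm_stage": [0, 5]}))

    def test_location_encoding(self):
        t = _clinical([0, 1, 0, 1]).table
        t["tumor_location_side"] = ["left", "right", "left", "right"]
        enc = ClinicalTable(t).encoded(("tumor_location_side",))
        assert list(enc["tumor_location_side"]) == [0, 1, 0, 1]
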