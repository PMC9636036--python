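"""Beta-binomial DMC calling, RE mapping, enrichment, marker tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylstate as ms
from methylstate.containers import ReferenceAtlas
from methylstate.dmc import REMap, genes_for_cpgs


def _count_atlas(rng, p_a, p_b, coverage=100, n_rep=4, spacing=2000,
                 classes=("TIIC-DC", "PBMC-DC")):
    """Two-class atlas with per-CpG binomial counts at the given proportions."""
    p_a, p_b = np.asarray(p_a, float), np.asarray(p_b, float)
    n = len(p_a)
    ids = pd.Index([f"chr1:{spacing * (i + 1)}" for i in range(n)])
    cols, labels, meths, totals = [], [], [], []
    for cls, p in zip(classes, (p_a, p_b)):
        for r in range(n_rep):
            cov = rng.poisson(coverage, n) + 1
            cols.append(f"{cls}.{r}")
            labels.append(cls)
            totals.append(cov)
            meths.append(rng.binomial(cov, p))
    sample_ids = pd.Index(cols)
    return ReferenceAtlas(
        cpg_ids=ids, sample_ids=sample_ids,
        methylated=pd.DataFrame(np.column_stack(meths), index=ids, columns=cols),
        total=pd.DataFrame(np.column_stack(totals), index=ids, columns=cols),
        class_labels=pd.Series(labels, index=sample_ids),
    )


class TestCallDmcs:
    def test_identical_counts_not_differential(self):
        rng = np.random.default_rng(0)
        ids = pd.Index([f"chr1:{2000 * (i + 1)}" for i in range(5)])
        cov = pd.DataFrame(100, index=ids, columns=[f"s{i}" for i in range(4)])
        meth = pd.DataFrame(40, index=ids, columns=cov.columns)
        atlas = ReferenceAtlas(
            cpg_ids=ids, sample_ids=cov.columns, methylated=meth, total=cov,
            class_labels=pd.Series(["TIIC-DC", "TIIC-DC", "PBMC-DC", "PBMC-DC"],
                                   index=cov.columns),
        )
        res = ms.call_dmcs(atlas, "TIIC-DC", "PBMC-DC", return_all=True)
        assert (res["effect"] == 0).all()
        assert (res["p"] > 0.99).all()

    def test_power_at_planted_effect(self):
        # delta 0.3 at coverage 100 with 4v4 replicates: essentially always called
        detected = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 40
            p_b = np.full(n, 0.35)
            atlas = _count_atlas(rng, p_b + 0.3, p_b)
            res = ms.call_dmcs(atlas, "TIIC-DC", "PBMC-DC", p_threshold=0.001)
            detected.append(len(res) / n)
        assert np.mean(detected) >= 0.95

    def test_type_i_error_controlled_on_null(self):
        rng = np.random.default_rng(1)
        n = 10_000
        p = np.clip(rng.beta(2, 2, n), 0.05, 0.95)
        atlas = _count_atlas(rng, p, p, coverage=60)
        res = ms.call_dmcs(atlas, "TIIC-DC", "PBMC-DC", p_threshold=0.01)
        assert len(res) / n <= 0.02

    def test_direction_annotation(self):
        rng = np.random.default_rng(2)
        p_b = np.full(10, 0.7)
        atlas = _count_atlas(rng, p_b - 0.4, p_b)
        res = ms.call_dmcs(atlas, "TIIC-DC", "PBMC-DC", p_threshold=0.001)
        assert (res["direction"] == "hypo-in-TIIC").all()
        assert (res["category"] == "TIIC-PBMC").all()

    def test_few_replicates_rejected(self):
        rng = np.random.default_rng(3)
        atlas = _count_atlas(rng, [0.5], [0.5], n_rep=1)
        with pytest.raises(ValueError, match="replicates"):
            ms.call_dmcs(atlas, "TIIC-DC", "PBMC-DC")

    def test_count_data_required(self, rng):
        ids = pd.Index(["chr1:100"])
        cols = pd.Index(["a.1", "a.2", "b.1", "b.2"])
        atlas = ReferenceAtlas(
            cpg_ids=ids, sample_ids=cols,
            betas=pd.DataFrame(0.5, index=ids, columns=cols),
            class_labels=pd.Series(["a", "a", "b", "b"], index=cols),
        )
        with pytest.raises(ValueError, match="count data"):
            ms.call_dmcs(atlas, "a", "b")


class TestMapCpgsToRes:
    RE = REMap(intervals=[("chr1", 2000, 2100, "re1")], re_targets={"re1": "G1"})

    @pytest.mark.parametrize(
        "pos,mapped",
        [
            (1000, True),   # gap 1000 <= 1250
            (100, False),   # gap 1900
            (750, True),    # gap exactly 1250, inclusive
            (749, False),   # gap 1251
            (2050, True),   # inside
            (3349, True),   # right side: 3349 - 2099 = 1250
            (3350, False),
        ],
    )
    def test_window_boundaries(self, pos, mapped):
        out = ms.map_cpgs_to_res([f"chr1:{pos}"], self.RE, window_bp=1250)
        assert bool(out[f"chr1:{pos}"]) == mapped

    def test_agrees_with_brute_force_scan(self, rng):
        intervals, targets = [], {}
        for i in range(1000):
            start = int(rng.integers(0, 500_000))
            end = start + int(rng.integers(50, 400))
            intervals.append(("chr1", start, end, f"re{i}"))
            targets[f"re{i}"] = f"G{i % 40}"
        remap = REMap(intervals=intervals, re_targets=targets)
        cpgs = [f"chr1:{int(rng.integers(0, 500_000))}" for _ in range(300)]
        out = ms.map_cpgs_to_res(cpgs, remap, window_bp=1250)
        for ident in cpgs:
            pos = int(ident.split(":")[1])
            expected = {
                (rid, targets[rid])
                for chrom, s, e, rid in intervals
                if max(s - pos, pos - (e - 1), 0) <= 1250
            }
            assert out[ident] == expected

    def test_unknown_chromosome_named(self):
        with pytest.raises(ValueError, match="chrZ"):
            ms.map_cpgs_to_res(["chrZ:100"], self.RE, known_chroms={"chr1"})


class TestEnrichGo:
    def test_exact_full_overlap_probability(self):
        background = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        target = set(term)
        res = ms.enrich_go(target, background, {"T": term})
        # drawing all 5 term genes in 5 draws from 20: 1 / C(20,5)
        assert res.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_term_equal_to_background_p_one(self):
        background = {f"g{i}" for i in range(10)}
        res = ms.enrich_go({"g0"}, background, {"T": set(background)})
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_single_term_bh_identity(self):
        background = {f"g{i}" for i in range(12)}
        res = ms.enrich_go({"g0", "g1"}, background, {"T": {"g0", "g1", "g2"}})
        assert res.loc[0, "adj_p"] == pytest.approx(res.loc[0, "p"])

    def test_matches_exhaustive_enumeration_small_universe(self):
        from itertools import combinations

        background = set("abcdefgh")  # N=8
        term = set("abc")
        target = set("abde")
        res = ms.enrich_go(target, background, {"T": term})
        k_obs = len(term & target)
        total = hits = 0
        for draw in combinations(sorted(background), len(target)):
            total += 1
            if len(term & set(draw)) >= k_obs:
                hits += 1
        assert res.loc[0, "p"] == pytest.approx(hits / total, rel=1e-12)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not in background"):
            ms.enrich_go({"x"}, {"a", "b"}, {"T": {"a"}})

    def test_restrict_to_limits_terms(self):
        background = {f"g{i}" for i in range(10)}
        sets = {"T1": {"g0"}, "T2": {"g1"}}
        res = ms.enrich_go({"g0"}, background, sets, restrict_to={"T1"})
        assert list(res["term"]) == ["T1"]


class TestSignatureCategories:
    def test_planted_state_dmcs_fall_in_tiic_pbmc_category(
        self, atlas, reference, combined_signature
    ):
        _, truth = reference
        cats = ms.categorize_signature_dmcs(combined_signature, atlas)
        planted = set().union(*truth.planted_state_dmcs.values())
        planted_in_sig = planted & set(combined_signature.cpg_ids)
        recall = len(cats["TIIC-PBMC"] & planted_in_sig) / len(planted_in_sig)
        assert recall >= 0.9

    def test_single_mode_signature_has_sparse_tiic_pbmc_category(self, atlas,
                                                                 combined_signature):
        # markers of a tumor-compartment class are inherently differential
        # against the blood compartment too, so the single-mode count is not
        # zero; the qualitative contrast is what the design predicts
        sig_t = ms.select_signature_cpgs(atlas, mode="tiic")
        cats_t = ms.categorize_signature_dmcs(sig_t, atlas)
        cats_c = ms.categorize_signature_dmcs(combined_signature, atlas)
        assert len(cats_t["TIIC-PBMC"]) < 0.5 * len(cats_c["TIIC-PBMC"])


class TestMarkerHypomethylation:
    def _fixture(self, rng, delta=-0.3, n_marker=12, n_other=30):
        """DMCs near REs of one marker gene plus unrelated DMCs."""
        p_b = np.concatenate([np.full(n_marker, 0.75),
                              np.clip(rng.beta(2, 2, n_other), 0.05, 0.95)])
        p_a = p_b.copy()
        p_a[:n_marker] += delta
        p_a[n_marker:] = np.clip(p_a[n_marker:] - 0.35, 0.02, 0.98)
        atlas = _count_atlas(rng, p_a, p_b, coverage=150, n_rep=4)
        intervals = []
        targets = {}
        for i in range(n_marker):
            pos = 2000 * (i + 1)
            intervals.append(("chr1", pos + 300, pos + 400, f"re{i}"))
            targets[f"re{i}"] = "CCR7"
        remap = REMap(intervals=intervals, re_targets=targets)
        dmcs = ms.call_dmcs(atlas, "TIIC-DC", "PBMC-DC", p_threshold=0.001)
        return dmcs, remap

    def test_planted_hypomethylation_detected(self, rng):
        dmcs, remap = self._fixture(rng)
        results = {r.gene: r for r in ms.marker_hypomethylation_test(dmcs, remap)}
        ccr7 = results["CCR7"]
        assert ccr7.testable
        assert ccr7.mean_difference < 0
        assert ccr7.direction == "hypo-in-TIIC"
        assert ccr7.p_value < 0.01

    def test_absent_marker_untestable_with_reason(self, rng):
        dmcs, remap = self._fixture(rng)
        results = {r.gene: r for r in ms.marker_hypomethylation_test(dmcs, remap)}
        assert not results["CD40"].testable
        assert "no REs" in results["CD40"].reason

    def test_il12_expands_to_both_subunits(self, rng):
        dmcs, remap = self._fixture(rng)
        remap.re_targets["re0"] = "IL12A"
        remap.re_targets["re1"] = "IL12B"
        results = {r.gene: r for r in ms.marker_hypomethylation_test(dmcs, remap)}
        assert results["IL12"].n_dmcs >= 1 or not results["IL12"].testable

    def test_paired_t_matches_scipy(self, rng):
        dmcs, remap = self._fixture(rng)
        results = {r.gene: r for r in ms.marker_hypomethylation_test(dmcs, remap)}
        ccr7 = results["CCR7"]
        mapping = ms.map_cpgs_to_res(list(dmcs["cpg_id"]), remap, window_bp=1250)
        rows = dmcs.loc[[bool(mapping[c]) for c in dmcs["cpg_id"]]]
        t, p = stats.ttest_rel(rows["mean_a"], rows["mean_b"])
        assert ccr7.statistic == pytest.approx(float(t))
        assert ccr7.p_value == pytest.approx(float(p))


class TestGenesForCpgs:
    def test_gene_level_dedup(self):
        mapping = {"c1": {("r1", "G1"), ("r2", "G1")}, "c2": {("r3", "G2")}}
        assert genes_for_cpgs(mapping) == {"G1", "G2"}
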