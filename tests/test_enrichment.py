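import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainenrich import (
    AtlasSimSpec,
    GeneRegionMatrix,
    bh_fdr,
    build_reference,
    enrich_all_regions,
    enrich_regions_of_interest,
    mwu_pvalue,
    region_auroc,
    simulate_atlas,
)
from oracles import auroc_pairwise, bh_stepup, mwu_enumeration


class TestRegionAuroc:
    def test_set_occupies_top_ranks(self):
        scores = {"g1": 3.0, "g2": 1.0, "g3": 2.0, "g4": 0.0}
        auroc, u, n_set, n_bg = region_auroc(scores, ["g1", "g3"])
        assert auroc == pytest.approx(1.0)
        assert (n_set, n_bg) == (2, 2)

    def test_interleaved_set(self):
        scores = {"g1": 3.0, "g2": 2.0, "g3": 1.0, "g4": 0.0}
        auroc, u, *_ = region_auroc(scores, ["g1", "g3"])
        assert auroc == pytest.approx(0.75)
        assert u == pytest.approx(3.0)

    def test_complement_reflection(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(20)]
        scores = dict(zip(genes, rng.normal(size=20)))
        a_set, *_ = region_auroc(scores, genes[:6])
        a_bg, *_ = region_auroc(scores, genes[6:])
        assert a_set + a_bg == pytest.approx(1.0)

    def test_matches_pairwise_oracle_with_and_without_ties(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            n = rng.integers(5, 50)
            genes = [f"g{i}" for i in range(n)]
            vals = rng.normal(size=n)
            if trial % 2:  # force ties
                vals = np.round(vals, 1)
            scores = dict(zip(genes, vals))
            n_set = int(rng.integers(1, min(10, n)))
            set_genes = set(rng.choice(genes, n_set, replace=False))
            auroc, *_ = region_auroc(scores, set_genes)
            assert abs(auroc - auroc_pairwise(scores, set_genes)) < 1e-12

    def test_missing_scores_excluded(self):
        scores = {"g1": 3.0, "g2": np.nan, "g3": 1.0}
        auroc, u, n_set, n_bg = region_auroc(scores, ["g1", "g2"])
        assert (n_set, n_bg) == (1, 1)
        assert auroc == pytest.approx(1.0)


class TestMwuPvalue:
    def test_exact_maximal_u_two_by_two(self):
        # U = 4 is maximal for 2 vs 2: two-sided p = 2 * (1 / C(4,2)) = 1/3
        p = mwu_pvalue(4, 2, 2)
        assert p == pytest.approx(2 / 6)

    def test_null_center_continuity_capped(self):
        # AUROC 0.5 with equal n: U at the null mean
        p = mwu_pvalue(12.5, 5, 5)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_set,n_bg", [(2, 3), (3, 3), (4, 5), (6, 6), (2, 8)])
    def test_exact_matches_enumeration(self, n_set, n_bg):
        rng = np.random.default_rng(n_set * 10 + n_bg)
        values = list(rng.normal(size=n_set + n_bg))
        ranks = stats.rankdata(values)
        u = ranks[:n_set].sum() - n_set * (n_set + 1) / 2
        for alt in ("two-sided", "greater", "less"):
            p_impl = mwu_pvalue(u, n_set, n_bg, alternative=alt)
            p_enum = mwu_enumeration(values, n_set, u, alternative=alt)
            assert p_impl == pytest.approx(p_enum, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n12(self):
        # moderate splits, exhaustive over every achievable U
        for n_set in range(4, 9):
            n_bg = 12 - n_set
            for u in range(n_set * n_bg + 1):
                p_exact = mwu_pvalue(u, n_set, n_bg)
                p_approx = mwu_pvalue(u, n_set, n_bg, exact_threshold=0)
                assert abs(p_exact - p_approx) < 0.02


    def test_agrees_with_scipy_on_raw_samples(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        ranks = stats.rankdata(np.concatenate([x, y]))
        u = ranks[:30].sum() - 30 * 31 / 2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        p = mwu_pvalue(u, 30, 40, counts)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(p_scipy, rel=1e-6)


class TestBhFdr:
    def test_hand_stepup_example(self):
        out = bh_fdr([0.01, 0.02, 0.04, 0.5])
        assert out == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(1e-8, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bh_stepup(p), atol=0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestEnrichAllRegions:
    def test_one_row_per_region(self, toy_reference):
        res = enrich_all_regions(toy_reference, ["G0", "G1"])
        assert len(res) == len(toy_reference.regions)
        assert res["p_fdr"].ge(res["p"]).all()
        assert sorted(res["brainwide_rank"]) == [1, 2, 3]

    def test_planted_region_ranks_first(self):
        hits = 0
        for seed in range(5):
            bundles, truth = simulate_atlas(
                AtlasSimSpec(n_genes=500, n_regions=10, planted_set_size=50, seed=seed)
            )
            ref = build_reference(bundles)
            res = enrich_all_regions(ref, truth["planted_genes"])
            top = res.loc[res["brainwide_rank"] == 1, "region"].iloc[0]
            hits += top == truth["planted_region"]
        assert hits == 5

    def test_auroc_u_identity(self, toy_reference):
        res = enrich_all_regions(toy_reference, ["G0", "G1", "G2"])
        recomputed = res["u"] / (res["n_set"] * res["n_background"])
        assert np.allclose(res["auroc"], recomputed)


class TestRegionsOfInterest:
    def test_unprofiled_region_flagged(self, toy_reference):
        res = enrich_regions_of_interest(
            toy_reference, ["G0", "G1"], ["r1", "solitary nucleus"]
        )
        status = res.set_index("region")["status"]
        assert status["r1"] == "ok"
        assert status["solitary nucleus"] == "not_profiled"

    def test_consistent_with_full_run(self, toy_reference):
        full = enrich_all_regions(toy_reference, ["G0", "G1"])
        roi = enrich_regions_of_interest(
            toy_reference, ["G0", "G1"], list(toy_reference.regions)
        )
        merged = full.merge(roi, on="region", suffixes=("_full", "_roi"))
        assert np.allclose(merged["auroc_full"], merged["auroc_roi"])
        assert (merged["brainwide_rank_full"] == merged["brainwide_rank_roi"]).all()

    def test_empty_roi_is_error(self, toy_reference):
        with pytest.raises(ValueError):
            enrich_regions_of_interest(toy_reference, ["G0"], [])

    def test_small_planted_set_detected_in_roi(self):
        hits = 0
        for seed in range(10):
            bundles, truth = simulate_atlas(
                AtlasSimSpec(
                    n_genes=400, n_regions=20, planted_set_size=6,
                    effect=1.5, seed=100 + seed,
                )
            )
            ref = build_reference(bundles)
            res = enrich_regions_of_interest(
                ref, truth["planted_genes"], [truth["planted_region"]]
            )
            hits += res["p"].iloc[0] < 0.05
        assert hits >= 8
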