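import numpy as np
import pandas as pd
import pytest

from brainenrich import (
    AtlasSimSpec,
    GeneRegionMatrix,
    ProbeExpressionBundle,
    ValidationError,
    aggregate_samples_by_region,
    average_donors,
    build_reference,
    collapse_probes_to_genes,
    rank_within_region,
    simulate_atlas,
    zscore_across_regions,
)


def expr_matrix(values, genes, cols):
    return GeneRegionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols), stage="expression"
    )


class TestCollapseProbes:
    def test_mean_of_two_probes(self, toy_bundle):
        m = collapse_probes_to_genes(toy_bundle)
        assert m.values.loc["GENEA", "s1"] == pytest.approx(3.0)  # mean(2, 4)

    def test_single_probe_passes_through(self, toy_bundle):
        m = collapse_probes_to_genes(toy_bundle)
        assert m.values.loc["GENEB", "s2"] == pytest.approx(2.0)

    def test_missing_values_excluded_from_mean(self):
        expr = pd.DataFrame(
            {"s1": [1.0, np.nan, 5.0]}, index=["p1", "p2", "p3"]
        )
        bundle = ProbeExpressionBundle(
            donor_id="d", expression=expr, sample_region={"s1": "r"},
            probe_gene={"p1": "G", "p2": "G", "p3": "G"},
        )
        m = collapse_probes_to_genes(bundle)
        assert m.values.loc["G", "s1"] == pytest.approx(np.nanmean([1.0, np.nan, 5.0]))

    def test_no_mapped_probes_is_error(self, toy_bundle):
        toy_bundle.probe_gene = {}
        with pytest.raises(ValidationError):
            collapse_probes_to_genes(toy_bundle)


class TestAggregateByRegion:
    def test_region_mean(self):
        m = expr_matrix([[1.0, 3.0]], ["G"], ["s1", "s2"])
        out = aggregate_samples_by_region(m, {"s1": "R", "s2": "R"})
        assert out.values.loc["G", "R"] == pytest.approx(2.0)

    def test_composite_pools_samples_before_mean(self):
        m = expr_matrix([[2.0, 4.0, 6.0]], ["G"], ["s1", "s2", "s3"])
        sample_region = {"s1": "R1", "s2": "R2", "s3": "R2"}
        out = aggregate_samples_by_region(m, sample_region, {"C": ["R1", "R2"]})
        # pooled mean(2, 4, 6), not mean of member means (mean(2, 5) = 3.5)
        assert out.values.loc["G", "C"] == pytest.approx(4.0)
        assert {"R1", "R2", "C"} <= set(out.values.columns)

    def test_composite_mean_of_member_means_switch(self):
        m = expr_matrix([[2.0, 4.0, 6.0]], ["G"], ["s1", "s2", "s3"])
        sample_region = {"s1": "R1", "s2": "R2", "s3": "R2"}
        out = aggregate_samples_by_region(
            m, sample_region, {"C": ["R1", "R2"]}, pool_samples=False
        )
        assert out.values.loc["G", "C"] == pytest.approx(3.5)

    def test_identical_region_names_pool_into_one_column(self):
        # hemisphere-duplicated regions carry identical names and merge
        m = expr_matrix([[1.0, 3.0]], ["G"], ["left", "right"])
        out = aggregate_samples_by_region(m, {"left": "CeA", "right": "CeA"})
        assert list(out.values.columns) == ["CeA"]


class TestRankWithinRegion:
    def test_basic_ranks(self):
        m = expr_matrix([[0.1], [0.9], [0.5]], ["a", "b", "c"], ["R"])
        out = rank_within_region(m)
        assert out.values["R"].tolist() == [1.0, 3.0, 2.0]

    def test_midranks_for_ties(self):
        m = expr_matrix([[0.1], [0.5], [0.5], [0.9]], list("abcd"), ["R"])
        out = rank_within_region(m)
        assert out.values["R"].tolist() == [1.0, 2.5, 2.5, 4.0]

    def test_tie_free_column_is_permutation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 1))
        m = expr_matrix(vals, [f"g{i}" for i in range(30)], ["R"])
        ranks = rank_within_region(m).values["R"].to_numpy()
        # sort-based oracle: position in the sorted order
        oracle = np.empty(30)
        oracle[np.argsort(vals[:, 0])] = np.arange(1, 31)
        assert np.array_equal(np.sort(ranks), np.arange(1, 31))
        assert np.array_equal(ranks, oracle)

    def test_missing_entries_reduce_n(self):
        m = expr_matrix([[0.1], [np.nan], [0.5]], list("abc"), ["R"])
        out = rank_within_region(m)
        assert out.values["R"].tolist()[0] == 1.0
        assert np.isnan(out.values["R"].iloc[1])
        assert out.values["R"].iloc[2] == 2.0

    def test_too_few_observations_names_region(self):
        m = expr_matrix([[0.1], [np.nan]], ["a", "b"], ["lonely"])
        with pytest.raises(ValidationError, match="lonely"):
            rank_within_region(m)


class TestZscore:
    def test_simple_row(self):
        m = GeneRegionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["G"], columns=list("abc")),
            stage="ranked",
        )
        out = zscore_across_regions(m)
        assert out.values.loc["G"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_becomes_zero_and_flagged(self):
        m = GeneRegionMatrix(
            values=pd.DataFrame([[5.0, 5.0, 5.0]], index=["G"], columns=list("abc")),
            stage="ranked",
        )
        out = zscore_across_regions(m)
        assert out.values.loc["G"].tolist() == [0.0, 0.0, 0.0]
        assert "G" in out.zero_variance_genes

    def test_random_rows_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        m = GeneRegionMatrix(
            values=pd.DataFrame(rng.normal(size=(50, 12))), stage="ranked"
        )
        out = zscore_across_regions(m)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-9
        assert np.abs(out.values.std(axis=1, ddof=1) - 1).max() < 1e-9


class TestAverageDonors:
    def z(self, data, genes, regions):
        return GeneRegionMatrix(
            values=pd.DataFrame(data, index=genes, columns=regions), stage="zscored"
        )

    def test_two_donor_mean_and_count(self):
        d1 = self.z([[0.5]], ["G"], ["R"])
        d2 = self.z([[1.5]], ["G"], ["R"])
        out = average_donors([d1, d2])
        assert out.values.loc["G", "R"] == pytest.approx(1.0)
        assert out.n_donors_per_cell.loc["G", "R"] == 2

    def test_region_in_one_donor_only(self):
        d1 = self.z([[0.5, -0.5]], ["G"], ["R1", "R2"])
        d2 = self.z([[1.0]], ["G"], ["R1"])
        out = average_donors([d1, d2])
        assert out.values.loc["G", "R2"] == pytest.approx(-0.5)
        assert out.n_donors_per_cell.loc["G", "R2"] == 1

    def test_single_donor_identity(self):
        d1 = self.z([[0.5, -0.5]], ["G"], ["R1", "R2"])
        out = average_donors([d1])
        pd.testing.assert_frame_equal(
            out.values, d1.values, check_names=False
        )
        assert (out.n_donors_per_cell == 1).all().all()

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            average_donors([])


def test_full_pipeline_is_deterministic():
    spec = AtlasSimSpec(n_genes=200, n_regions=6, planted_set_size=20, seed=3)
    refs = []
    for _ in range(2):
        bundles, _ = simulate_atlas(spec)
        refs.append(build_reference(bundles))
    pd.testing.assert_frame_equal(refs[0].values, refs[1].values)


def test_planted_genes_peak_in_planted_region():
    """With a >= 1 SD shift, planted genes' donor-averaged z in the planted
    region exceeds their z in every other region."""
    spec = AtlasSimSpec(
        n_genes=400, n_regions=8, n_donors=3, planted_set_size=40,
        effect=1.0, noise_sd=1.0, seed=11,
    )
    bundles, truth = simulate_atlas(spec)
    ref = build_reference(bundles)
    planted_z = ref.values.loc[truth["planted_genes"]]
    mean_z = planted_z.mean(axis=0)
    assert mean_z.idxmax() == truth["planted_region"]
    assert (mean_z[truth["planted_region"]] > mean_z.drop(truth["planted_region"])).all()
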