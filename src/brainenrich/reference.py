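"""Build the gene x region reference matrix from per-donor atlas bundles.

The pipeline is, per donor: probe values are mean-collapsed to gene symbols,
samples sharing a region name are mean-averaged into one regional profile
(composite regions pool their member-region samples first), each region's
gene vector is converted to ascending midranks, each gene's rank vector is
z-scored across regions, and finally the per-donor z-score matrices are
averaged cell-wise across donors.  The resulting donor-averaged matrix is
the substrate for all regional enrichment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import ProbeExpressionBundle, ValidationError

__all__ = [
    "GeneRegionMatrix",
    "collapse_probes_to_genes",
    "aggregate_samples_by_region",
    "rank_within_region",
    "zscore_across_regions",
    "average_donors",
    "build_reference",
    "write_reference",
    "read_reference",
]

STAGES = ("expression", "ranked", "zscored", "donor_averaged")


@dataclass
class GeneRegionMatrix:
    """Gene x column matrix with stage-dependent value semantics.

    ``stage`` is one of ``expression`` (raw means; columns may be samples or
    regions), ``ranked`` (within-column midranks), ``zscored`` (per-gene
    z-scores of ranks across regions) or ``donor_averaged`` (mean z across
    donors, with ``n_donors_per_cell`` recording per-cell donor counts).
    """

    values: pd.DataFrame
    stage: str
    n_donors_per_cell: pd.DataFrame | None = None
    zero_variance_genes: tuple[str, ...] = ()
    low_coverage_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


def _require_stage(matrix: GeneRegionMatrix, stage: str) -> None:
    if matrix.stage != stage:
        raise ValueError(f"expected stage {stage!r}, got {matrix.stage!r}")


def collapse_probes_to_genes(bundle: ProbeExpressionBundle) -> GeneRegionMatrix:
    """Mean-average probe rows into one row per gene symbol.

    Missing probe values are ignored in the mean; probes with no gene
    mapping are dropped.
    """
    mapped = [p for p in bundle.expression.index if p in bundle.probe_gene]
    if not mapped:
        raise ValidationError(f"donor {bundle.donor_id}: no probes map to genes")
    sub = bundle.expression.loc[mapped]
    genes = pd.Index([bundle.probe_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes, sort=True).mean()
    return GeneRegionMatrix(values=collapsed, stage="expression")


def aggregate_samples_by_region(
    matrix: GeneRegionMatrix,
    sample_region: Mapping[str, str],
    merge_map: Mapping[str, Sequence[str]] | None = None,
    *,
    keep_members: bool = True,
    pool_samples: bool = True,
) -> GeneRegionMatrix:
    """Average samples into one column per region name.

    Composite regions from ``merge_map`` pool all member-region samples
    before averaging (default), so members with more samples weigh more;
    ``pool_samples=False`` averages the member-region means instead.
    Member regions are also retained as standalone columns when
    ``keep_members`` is true.
    """
    _require_stage(matrix, "expression")
    region_samples: dict[str, list[str]] = {}
    for sample in matrix.values.columns:
        region = sample_region.get(sample)
        if region is not None:
            region_samples.setdefault(region.strip(), []).append(sample)

    cols: dict[str, pd.Series] = {}
    for region, samples in region_samples.items():
        cols[region] = matrix.values[samples].mean(axis=1)

    if merge_map:
        for composite, members in merge_map.items():
            present = [m.strip() for m in members if m.strip() in region_samples]
            absent = [m for m in members if m.strip() not in region_samples]
            if absent:
                import logging

                logging.getLogger(__name__).warning(
                    "composite %s: member regions not in bundle: %s", composite, absent
                )
            if not present:
                continue
            if pool_samples:
                pooled = [s for m in present for s in region_samples[m]]
                cols[composite] = matrix.values[pooled].mean(axis=1)
            else:
                cols[composite] = pd.concat(
                    [cols[m] for m in present], axis=1
                ).mean(axis=1)
            if not keep_members:
                for m in present:
                    cols.pop(m, None)

    values = pd.DataFrame(cols)
    values.index.name = "gene"
    return GeneRegionMatrix(values=values, stage="expression")


def rank_within_region(matrix: GeneRegionMatrix) -> GeneRegionMatrix:
    """Replace each region column by ascending midranks (lowest value -> 1).

    Ties receive the average of the tied positions; missing entries stay
    missing and reduce n for that column.
    """
    _require_stage(matrix, "expression")
    for region in matrix.values.columns:
        if matrix.values[region].notna().sum() < 2:
            raise ValidationError(
                f"region {region!r} has fewer than two observed genes"
            )
    ranked = matrix.values.rank(axis=0, method="average", na_option="keep")
    return GeneRegionMatrix(values=ranked, stage="ranked")


def zscore_across_regions(matrix: GeneRegionMatrix) -> GeneRegionMatrix:
    """Z-score each gene's rank vector across its non-missing regions.

    The sample (n-1) standard deviation is used.  Zero-variance rows become
    all-zero (neutral) and are flagged; genes observed in fewer than two
    regions become all-missing and are flagged.
    """
    _require_stage(matrix, "ranked")
    vals = matrix.values
    n_obs = vals.notna().sum(axis=1)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)

    z = vals.sub(mean, axis=0).div(sd, axis=0)
    zero_var = (sd == 0) & (n_obs >= 2)
    if zero_var.any():
        z.loc[zero_var] = vals.loc[zero_var].notna().astype(float) * 0.0
        z.loc[zero_var] = z.loc[zero_var].where(vals.loc[zero_var].notna())
    low = n_obs < 2
    if low.any():
        z.loc[low] = np.nan
    return GeneRegionMatrix(
        values=z,
        stage="zscored",
        zero_variance_genes=tuple(vals.index[zero_var]),
        low_coverage_genes=tuple(vals.index[low]),
    )


def average_donors(matrices: Sequence[GeneRegionMatrix]) -> GeneRegionMatrix:
    """Average z-score matrices cell-wise across donors.

    A cell's mean is taken over the donors in which it is present;
    ``n_donors_per_cell`` records the contributing counts.  Genes or regions
    present in no donor are absent from the output.
    """
    if not matrices:
        raise ValueError("average_donors requires at least one donor matrix")
    for m in matrices:
        _require_stage(m, "zscored")
    genes = sorted(set().union(*(m.values.index for m in matrices)))
    regions = sorted(set().union(*(m.values.columns for m in matrices)))
    total = pd.DataFrame(0.0, index=genes, columns=regions)
    count = pd.DataFrame(0, index=genes, columns=regions)
    for m in matrices:
        aligned = m.values.reindex(index=genes, columns=regions)
        present = aligned.notna()
        total += aligned.fillna(0.0)
        count += present.astype(int)
    with np.errstate(invalid="ignore"):
        avg = total.where(count > 0) / count.where(count > 0)
    keep_genes = count.sum(axis=1) > 0
    keep_regions = count.sum(axis=0) > 0
    avg = avg.loc[keep_genes, keep_regions]
    count = count.loc[keep_genes, keep_regions]
    avg.index.name = "gene"
    zero_var = tuple(
        sorted(set().union(*(m.zero_variance_genes for m in matrices)) & set(avg.index))
    )
    return GeneRegionMatrix(
        values=avg,
        stage="donor_averaged",
        n_donors_per_cell=count,
        zero_variance_genes=zero_var,
    )


def build_reference(
    bundles: Sequence[ProbeExpressionBundle],
    merge_map: Mapping[str, Sequence[str]] | None = None,
    *,
    keep_members: bool = True,
    pool_samples: bool = True,
) -> GeneRegionMatrix:
    """Run the full per-donor pipeline and average across donors."""
    per_donor = []
    for bundle in bundles:
        m = collapse_probes_to_genes(bundle)
        m = aggregate_samples_by_region(
            m, bundle.sample_region, merge_map,
            keep_members=keep_members, pool_samples=pool_samples,
        )
        m = rank_within_region(m)
        m = zscore_across_regions(m)
        per_donor.append(m)
    return average_donors(per_donor)


def write_reference(matrix: GeneRegionMatrix, path: str | Path) -> None:
    """Serialize a donor-averaged reference matrix as TSV (gene first column);
    the donor-count sidecar goes to ``<path>.n_donors.tsv``."""
    _require_stage(matrix, "donor_averaged")
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if matrix.n_donors_per_cell is not None:
        matrix.n_donors_per_cell.to_csv(
            path.with_name(path.name + ".n_donors.tsv"), sep="\t", index_label="gene"
        )


def read_reference(path: str | Path) -> GeneRegionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene")
    sidecar = path.with_name(path.name + ".n_donors.tsv")
    counts = None
    if sidecar.exists():
        counts = pd.read_csv(sidecar, sep="\t", index_col="gene")
    return GeneRegionMatrix(values=values, stage="donor_averaged", n_donors_per_cell=counts)
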