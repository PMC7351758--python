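"""Batch-stratified two-condition single-cell differential expression.

Each gene is tested per batch with a one-sided Mann-Whitney U in each
direction (food-deprived > fed, and <), and the per-batch p-values are
combined across strata with Fisher's method into meta p-values for up- and
down-regulation.  BH-FDR is applied per direction across all tested genes;
a gene's direction is the smaller-FDR direction when that FDR clears the
significance level.  Rank-based testing makes the result invariant to any
monotone transform of the expression scale (log-TPM, ln-CPM, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ValidationError
from .enrichment import bh_fdr
from .genesets import GeneSet
from .overlap import hypergeometric_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "CellMatrix",
    "read_cell_matrix",
    "filter_genes",
    "select_cells",
    "per_batch_de",
    "fisher_combine",
    "combine_strata",
    "run_fasting_de",
    "de_summary",
]

CONDITIONS = ("fed", "deprived")


@dataclass
class CellMatrix:
    """Gene x cell expression with per-cell condition / batch (and sex) labels."""

    values: pd.DataFrame
    condition: pd.Series
    batch: pd.Series
    sex: pd.Series | None = None
    name: str = "sc"

    def validate(self) -> "CellMatrix":
        cells = self.values.columns
        for label, series in (("condition", self.condition), ("batch", self.batch)):
            missing = cells.difference(series.index)
            if len(missing):
                raise ValidationError(
                    f"{self.name}: cells without {label} label: {list(missing[:5])}"
                )
        bad = set(self.condition.loc[cells]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"{self.name}: unknown conditions {sorted(bad)}")
        return self

    @property
    def batches(self) -> list:
        return sorted(self.batch.loc[self.values.columns].unique().tolist())


def read_cell_matrix(
    expression_path: str | Path,
    metadata_path: str | Path,
    *,
    name: str | None = None,
    condition_labels: Mapping[str, str] | None = None,
) -> CellMatrix:
    """Read a dense gene x cell TSV plus a cell-metadata TSV.

    The metadata table needs columns ``cell``, ``condition``, ``batch`` and
    optionally ``sex``.  ``condition_labels`` maps the file's condition
    strings onto the canonical ``fed`` / ``deprived`` labels.
    """
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("cell")
    cond = meta["condition"]
    if condition_labels:
        cond = cond.map(lambda c: condition_labels.get(c, c))
    cm = CellMatrix(
        values=values,
        condition=cond,
        batch=meta["batch"],
        sex=meta["sex"] if "sex" in meta.columns else None,
        name=name or Path(expression_path).stem,
    )
    return cm.validate()


def filter_genes(matrix: CellMatrix, homolog_map: pd.DataFrame | Iterable[str]) -> CellMatrix:
    """Keep genes with a human homolog, any nonzero expression, and nonzero
    variance across cells; removal counts per criterion are logged."""
    if isinstance(homolog_map, pd.DataFrame):
        with_homolog = set(homolog_map["mouse"])
    else:
        with_homolog = set(homolog_map)
    vals = matrix.values
    has_homolog = vals.index.isin(with_homolog)
    arr = vals.to_numpy()
    nonzero = (arr != 0).any(axis=1)
    varying = arr.std(axis=1) > 0
    keep = has_homolog & nonzero & varying
    logger.info(
        "%s: removed %d genes without homolog, %d all-zero, %d zero-variance; %d retained",
        matrix.name, int((~has_homolog).sum()), int((~nonzero).sum()),
        int((~varying).sum()), int(keep.sum()),
    )
    if not keep.any():
        raise ValidationError(f"{matrix.name}: no genes survive filtering")
    return CellMatrix(
        values=vals.loc[keep], condition=matrix.condition, batch=matrix.batch,
        sex=matrix.sex, name=matrix.name,
    ).validate()


def select_cells(
    matrix: CellMatrix,
    batches: Sequence,
    *,
    sex: str | None = None,
    condition_labels: Mapping[str, str] | None = None,
) -> CellMatrix:
    """Subset to the requested batches (and optionally one sex).

    Every retained batch must contain cells of both conditions, mirroring
    the requirement that each stratum compares food-deprived to fed cells.
    """
    if not batches:
        raise ValidationError("no batches requested")
    batches = [str(b) for b in batches]
    cells = matrix.values.columns
    batch = matrix.batch.loc[cells].astype(str)
    known = set(batch)
    missing = [b for b in batches if b not in known]
    if missing:
        raise ValidationError(f"{matrix.name}: unknown batches {missing}")
    mask = batch.isin(batches)
    if sex is not None:
        if matrix.sex is None:
            raise ValidationError(f"{matrix.name}: no sex labels available")
        mask &= matrix.sex.loc[cells] == sex
    kept = cells[mask.to_numpy()]
    cond = matrix.condition.loc[kept]
    if condition_labels:
        cond = cond.map(lambda c: condition_labels.get(c, c))
    for b in batches:
        present = set(cond[batch.loc[kept] == b])
        if not {"fed", "deprived"} <= present:
            raise ValidationError(
                f"{matrix.name}: batch {b!r} lacks one condition (has {sorted(present)})"
            )
    return CellMatrix(
        values=matrix.values[kept], condition=cond, batch=matrix.batch,
        sex=matrix.sex, name=matrix.name,
    ).validate()


def per_batch_de(matrix: CellMatrix) -> pd.DataFrame:
    """One-sided Mann-Whitney p-value pairs per gene and batch.

    For each batch, deprived cells are compared to fed cells gene-wise;
    ``p_up`` tests deprived > fed, ``p_down`` the reverse.  Both are tie-
    and continuity-corrected tails of the same U statistic.  Returns a
    frame indexed by gene with MultiIndex columns (direction, batch).
    """
    cells = matrix.values.columns
    batch = matrix.batch.loc[cells].astype(str)
    cond = matrix.condition.loc[cells]
    out: dict[tuple[str, str], np.ndarray] = {}
    for b in sorted(batch.unique()):
        in_b = (batch == b).to_numpy()
        dep = matrix.values.loc[:, in_b & (cond == "deprived").to_numpy()].to_numpy()
        fed = matrix.values.loc[:, in_b & (cond == "fed").to_numpy()].to_numpy()
        if dep.shape[1] == 0 or fed.shape[1] == 0:
            raise ValidationError(f"{matrix.name}: batch {b!r} lacks one condition")
        res_up = stats.mannwhitneyu(dep, fed, axis=1, alternative="greater",
                                    method="asymptotic")
        res_down = stats.mannwhitneyu(dep, fed, axis=1, alternative="less",
                                      method="asymptotic")
        out[("p_up", b)] = np.clip(res_up.pvalue, 5e-324, 1.0)
        out[("p_down", b)] = np.clip(res_down.pvalue, 5e-324, 1.0)
    df = pd.DataFrame(out, index=matrix.values.index)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["direction", "batch"])
    return df


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X^2 = -2 sum(ln p) against chi-square with 2k df.

    Values are clamped at 1e-300 before the log for numeric safety.
    """
    p = np.asarray([v for v in p_values if not np.isnan(v)], dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.log(np.clip(p, 1e-300, 1.0)).sum()
    return float(min(max(stats.chi2.sf(x2, 2 * p.size), 5e-324), 1.0))


def combine_strata(per_stratum: pd.DataFrame) -> pd.DataFrame:
    """Combine per-stratum one-sided p pairs into meta p-values per gene.

    ``per_stratum`` is the (possibly concatenated) output of
    :func:`per_batch_de`; genes missing in a stratum contribute only their
    available strata (df = 2 x available count).
    """
    meta = {}
    for direction in ("p_up", "p_down"):
        block = per_stratum[direction]
        logp = -2.0 * np.log(np.clip(block.to_numpy(dtype=float), 1e-300, 1.0))
        k = block.notna().sum(axis=1).to_numpy()
        x2 = np.nansum(logp, axis=1)
        p = stats.chi2.sf(x2, 2 * k)
        meta["meta_" + direction] = np.clip(p, 5e-324, 1.0)
    out = pd.DataFrame(meta, index=per_stratum.index)
    out["n_strata"] = per_stratum["p_up"].notna().sum(axis=1)
    return out


def run_fasting_de(
    matrices: CellMatrix | Sequence[CellMatrix],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full DE meta-analysis over one or more batched cell matrices.

    Every (dataset, batch) pair is one stratum.  Returns a frame indexed by
    gene with per-stratum one-sided p's, Fisher meta p's per direction,
    per-direction BH-FDR over all tested genes, and the called direction
    (``up`` / ``down`` / ``none``).
    """
    if isinstance(matrices, CellMatrix):
        matrices = [matrices]
    blocks = []
    for m in matrices:
        pb = per_batch_de(m)
        pb.columns = pd.MultiIndex.from_tuples(
            [(d, f"{m.name}:{b}") for d, b in pb.columns], names=["direction", "stratum"]
        )
        blocks.append(pb)
    per_stratum = pd.concat(blocks, axis=1)
    result = combine_strata(per_stratum)
    result["fdr_up"] = bh_fdr(result["meta_p_up"].to_numpy())
    result["fdr_down"] = bh_fdr(result["meta_p_down"].to_numpy())
    direction = np.where(
        (result["fdr_up"] <= result["fdr_down"]) & (result["fdr_up"] < alpha), "up",
        np.where(result["fdr_down"] < alpha, "down", "none"),
    )
    result["direction"] = direction
    # keep per-stratum columns for reporting
    flat = per_stratum.copy()
    flat.columns = [f"{d}[{s}]" for d, s in per_stratum.columns]
    return pd.concat([flat, result], axis=1)


def de_summary(
    results: pd.DataFrame,
    gene_lists: Sequence[GeneSet],
    *,
    alpha: float = 0.05,
    human_to_mouse_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Genome-wide and per-list differential-expression proportions.

    A gene counts as DE when either direction's meta-FDR is below alpha.
    Per list, the DE fraction among list genes with data is reported along
    with an upper-tail hypergeometric enrichment p against the genome-wide
    rate (testing whether a list is disproportionately DE).
    """
    tested = list(results.index)
    is_de = (results["fdr_up"] < alpha) | (results["fdr_down"] < alpha)
    de_genes = set(results.index[is_de])
    rows = [
        dict(
            list="genome_wide", n_with_data=len(tested), n_de=len(de_genes),
            fraction_de=len(de_genes) / len(tested) if tested else 0.0,
            enrichment_p=np.nan,
        )
    ]
    for gs in gene_lists:
        symbols = list(gs.symbols)
        if human_to_mouse_map is not None:
            symbols = [human_to_mouse_map[s] for s in symbols if s in human_to_mouse_map]
        present = [s for s in symbols if s in results.index]
        n_de = sum(1 for s in present if s in de_genes)
        if present:
            res = hypergeometric_overlap(
                present, de_genes, tested, name_a=gs.name, name_b="de_genes"
            )
            enr_p = res.p_raw
        else:
            enr_p = np.nan
        rows.append(
            dict(
                list=gs.name, n_with_data=len(present), n_de=n_de,
                fraction_de=n_de / len(present) if present else 0.0,
                enrichment_p=enr_p,
            )
        )
    return pd.DataFrame(rows)
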