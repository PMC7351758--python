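"""Reading and validation of multi-donor expression-atlas bundles.

An atlas bundle follows the Allen Institute download layout: per donor, a
probe x sample expression matrix of normalized log intensities, a sample
annotation table mapping each sample to a named brain region, and a probe
annotation table mapping probes to gene symbols.  Column names for the
annotation tables are configurable; the defaults match that layout.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "ProbeExpressionBundle",
    "read_bundle",
    "write_bundle",
    "read_region_merge_map",
    "DEFAULT_COLUMNS",
]


class ParseError(ValueError):
    """An input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed inputs violate a structural invariant."""


#: default annotation-table column names (Allen-style download layout)
DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "region": "region",
    "probe_id": "probe_id",
    "gene_symbol": "gene_symbol",
}


def _delimiter_for(path: str | Path, delimiter: str | None = None) -> str:
    if delimiter is not None:
        return delimiter
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def _open_text(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _expression_has_header(path: str | Path, sep: str) -> bool:
    """A header row is assumed when the second field of line 1 is not numeric."""
    with _open_text(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\r\n").split(sep)
    if len(fields) < 2:
        raise ParseError(f"{path}: line 1 has fewer than two fields")
    try:
        float(fields[1])
    except ValueError:
        return True
    return False


@dataclass
class ProbeExpressionBundle:
    """One donor's probe x sample expression matrix plus annotations.

    ``expression`` rows are probe ids, columns sample ids.  Probes without a
    gene mapping are retained in the matrix but absent from ``probe_gene``.
    """

    donor_id: str
    expression: pd.DataFrame
    sample_region: dict[str, str]
    probe_gene: dict[str, str]
    n_dropped_samples: int = 0

    def validate(self) -> "ProbeExpressionBundle":
        if self.expression.index.duplicated().any():
            dup = self.expression.index[self.expression.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r} in expression matrix")
        missing = [c for c in self.expression.columns if c not in self.sample_region]
        if missing:
            raise ValidationError(
                f"samples without region annotation: {missing[:5]}"
            )
        if self.expression.shape[1] == 0:
            raise ValidationError(f"donor {self.donor_id}: zero usable samples")
        for sample, region in self.sample_region.items():
            if not isinstance(region, str) or not region.strip():
                raise ValidationError(f"sample {sample!r} has an empty region name")
        all_missing = self.expression.isna().all(axis=1)
        if all_missing.any():
            bad = self.expression.index[all_missing][0]
            raise ValidationError(f"probe {bad!r} has no observed values")
        return self

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.sample_region.values():
            seen.setdefault(r)
        return list(seen)


def read_bundle(
    expression_path: str | Path,
    sample_annot_path: str | Path,
    probe_annot_path: str | Path,
    donor_id: str,
    *,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> ProbeExpressionBundle:
    """Read one donor's expression bundle from the three-file atlas layout.

    The expression file is a delimited matrix with probe ids in the first
    column; a header row of sample ids is optional.  When headerless, sample
    ids are taken from the sample-annotation table in row order (the Allen
    convention).  Samples lacking a region annotation are dropped with a
    logged count; probes absent from the probe-annotation table stay in the
    matrix but are excluded from the probe->gene map.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    sep = _delimiter_for(expression_path, delimiter)
    has_header = _expression_has_header(expression_path, sep)
    try:
        expr = pd.read_csv(
            expression_path,
            sep=sep,
            header=0 if has_header else None,
            index_col=0,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{expression_path}: {exc}") from exc
    expr.index = expr.index.astype(str).str.strip()
    expr.index.name = None
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise ValidationError(f"duplicate probe id {dup!r} in {expression_path}")

    annot = pd.read_csv(sample_annot_path, sep=_delimiter_for(sample_annot_path, delimiter))
    for key in ("sample_id", "region"):
        if cols[key] not in annot.columns:
            raise ParseError(
                f"{sample_annot_path}: missing column {cols[key]!r}"
            )
    annot_ids = annot[cols["sample_id"]].astype(str).str.strip()
    regions = annot[cols["region"]]

    if not has_header:
        if len(annot) != expr.shape[1]:
            raise ValidationError(
                f"headerless expression matrix has {expr.shape[1]} sample columns "
                f"but the annotation table lists {len(annot)} samples"
            )
        expr.columns = list(annot_ids)
    else:
        expr.columns = [str(c).strip() for c in expr.columns]

    sample_region: dict[str, str] = {}
    for sid, region in zip(annot_ids, regions):
        if isinstance(region, str) and region.strip():
            sample_region[sid] = region.strip()

    usable = [c for c in expr.columns if c in sample_region]
    n_dropped = expr.shape[1] - len(usable)
    if n_dropped:
        logger.info(
            "donor %s: dropped %d of %d samples lacking region annotation",
            donor_id, n_dropped, expr.shape[1],
        )
    expr = expr[usable]
    sample_region = {c: sample_region[c] for c in usable}

    probes = pd.read_csv(probe_annot_path, sep=_delimiter_for(probe_annot_path, delimiter))
    for key in ("probe_id", "gene_symbol"):
        if cols[key] not in probes.columns:
            raise ParseError(f"{probe_annot_path}: missing column {cols[key]!r}")
    probe_gene: dict[str, str] = {}
    in_matrix = set(expr.index)
    for pid, sym in zip(
        probes[cols["probe_id"]].astype(str).str.strip(), probes[cols["gene_symbol"]]
    ):
        if pid in in_matrix and isinstance(sym, str) and sym.strip():
            probe_gene[pid] = sym.strip()

    bundle = ProbeExpressionBundle(
        donor_id=donor_id,
        expression=expr,
        sample_region=sample_region,
        probe_gene=probe_gene,
        n_dropped_samples=n_dropped,
    )
    return bundle.validate()


def write_bundle(bundle: ProbeExpressionBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle back to the three-file layout (round-trip inverse of
    :func:`read_bundle`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr_path = directory / "Expression.csv"
    sample_path = directory / "SampleAnnot.csv"
    probe_path = directory / "Probes.csv"
    bundle.expression.to_csv(expr_path, index_label="probe_id")
    pd.DataFrame(
        {
            "sample_id": list(bundle.sample_region),
            "region": list(bundle.sample_region.values()),
        }
    ).to_csv(sample_path, index=False)
    pd.DataFrame(
        {
            "probe_id": list(bundle.probe_gene),
            "gene_symbol": list(bundle.probe_gene.values()),
        }
    ).to_csv(probe_path, index=False)
    return {"expression": expr_path, "sample_annot": sample_path, "probe_annot": probe_path}


def read_region_merge_map(
    path: str | Path, *, delimiter: str | None = None
) -> dict[str, list[str]]:
    """Read a two-column (composite, member) table into a merge map.

    Duplicate (composite, member) pairs are deduplicated; a member region
    assigned to two different composites is a validation error.
    """
    sep = _delimiter_for(path, delimiter)
    merge: dict[str, list[str]] = {}
    owner: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two fields")
            composite, member = parts[0].strip(), parts[1].strip()
            if lineno == 1 and {composite.lower(), member.lower()} == {"composite", "member"}:
                continue  # optional header
            if member in owner and owner[member] != composite:
                raise ValidationError(
                    f"member region {member!r} assigned to both "
                    f"{owner[member]!r} and {composite!r}"
                )
            owner[member] = composite
            members = merge.setdefault(composite, [])
            if member not in members:
                members.append(member)
    return merge
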