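"""Gene-set containers, symbol normalization, filtering and matching.

Human symbols are upper-cased and antisense/intronic transcript suffixes
(``-AS`` / ``-IT``, optionally followed by digits) are stripped once so that
non-coding transcripts map onto the symbol of their protein-coding host
gene.  Mouse symbols are compared case-sensitively and left untouched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .atlas import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .reference import GeneRegionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "MatchedGeneSet",
    "normalize_symbol",
    "bonferroni_filter",
    "match_to_reference",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
]

_SUFFIX_RE = re.compile(r"-(?:AS|IT)\d*$")


def normalize_symbol(symbol: str, species: str = "human") -> str:
    """Normalize a gene symbol for matching.

    Human symbols are upper-cased, then one trailing ``-AS<digits?>`` or
    ``-IT<digits?>`` suffix is removed (applied once, not recursively).
    Mouse symbols are only whitespace-trimmed.
    """
    s = symbol.strip()
    if not s:
        raise ValueError("empty gene symbol")
    if species != "human":
        return s
    s = s.upper()
    stripped = _SUFFIX_RE.sub("", s)
    return stripped if stripped else s


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols.

    ``per_gene_p`` optionally maps a subset of the symbols to p-values in
    [0, 1] (e.g. exome burden tests).
    """

    name: str
    symbols: tuple[str, ...]
    provenance: str = ""
    per_gene_p: Mapping[str, float] | None = None
    species: str = "human"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError(f"gene set {self.name!r}: duplicate symbols")
        if self.per_gene_p is not None:
            extra = set(self.per_gene_p) - set(self.symbols)
            if extra:
                raise ValidationError(
                    f"gene set {self.name!r}: p-values for unknown symbols {sorted(extra)[:5]}"
                )
            for sym, p in self.per_gene_p.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(f"gene set {self.name!r}: p({sym}) = {p} outside [0, 1]")

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        *,
        provenance: str = "",
        per_gene_p: Mapping[str, float] | None = None,
        species: str = "human",
        normalize: bool = True,
    ) -> "GeneSet":
        """Build a set, normalizing and deduplicating symbols (order kept).

        When two input symbols normalize to the same name and both carry a
        p-value, the smaller p-value is kept.
        """
        norm: dict[str, None] = {}
        pmap: dict[str, float] = {}
        for sym in symbols:
            key = normalize_symbol(sym, species) if normalize else sym.strip()
            norm.setdefault(key)
            if per_gene_p is not None and sym in per_gene_p:
                p = float(per_gene_p[sym])
                pmap[key] = min(p, pmap.get(key, 1.0))
        return cls(
            name=name,
            symbols=tuple(norm),
            provenance=provenance,
            per_gene_p=pmap if per_gene_p is not None else None,
            species=species,
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)


@dataclass(frozen=True)
class MatchedGeneSet:
    """Partition of a gene set by membership in a reference matrix.

    ``reference_genes`` holds the reference matrix's own row names for the
    matched symbols (normally identical to ``matched``, but they can differ
    when the reference carries unnormalized symbols).
    """

    source: GeneSet
    matched: tuple[str, ...]
    unmatched: tuple[str, ...]
    reference_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.reference_genes:
            object.__setattr__(self, "reference_genes", self.matched)
        if set(self.matched) & set(self.unmatched):
            raise ValidationError("matched and unmatched overlap")
        if set(self.matched) | set(self.unmatched) != set(self.source.symbols):
            raise ValidationError("matched + unmatched do not cover the source set")

    @property
    def name(self) -> str:
        return self.source.name


def bonferroni_filter(gene_set: GeneSet, m: int = 20000, alpha: float = 0.05) -> GeneSet:
    """Retain symbols whose Bonferroni-corrected p (p*m, capped at 1) is <= alpha.

    The genome-wide multiplier defaults to an estimate of 20,000 tested genes.
    """
    if gene_set.per_gene_p is None:
        raise ValueError(f"gene set {gene_set.name!r} has no per-gene p-values")
    missing = [s for s in gene_set.symbols if s not in gene_set.per_gene_p]
    if missing:
        raise ValueError(
            f"gene set {gene_set.name!r}: no p-value for {missing[:5]}"
        )
    kept = tuple(
        s for s in gene_set.symbols if min(gene_set.per_gene_p[s] * m, 1.0) <= alpha
    )
    return GeneSet(
        name=gene_set.name + "_bonferroni",
        symbols=kept,
        provenance=gene_set.provenance,
        per_gene_p={s: gene_set.per_gene_p[s] for s in kept},
        species=gene_set.species,
    )


def match_to_reference(gene_set: GeneSet, reference: "GeneRegionMatrix") -> MatchedGeneSet:
    """Partition a set by membership in a reference matrix's gene vocabulary.

    Both sides are normalized before comparison.  Zero matches is an error
    because every downstream enrichment statistic would be undefined.
    """
    if reference.stage != "donor_averaged":
        raise ValueError("reference must be at stage 'donor_averaged'")
    ref_lookup: dict[str, str] = {}
    for g in reference.values.index:
        ref_lookup.setdefault(normalize_symbol(str(g), gene_set.species), str(g))
    matched, unmatched = [], []
    for sym in gene_set.symbols:
        key = normalize_symbol(sym, gene_set.species)
        (matched if key in ref_lookup else unmatched).append(sym)
    if not matched:
        raise ValidationError(
            f"gene set {gene_set.name!r}: no symbols match the reference"
        )
    logger.info(
        "gene set %s: %d of %d symbols matched the reference (%.1f%%)",
        gene_set.name, len(matched), len(gene_set), 100 * len(matched) / len(gene_set),
    )
    ref_genes = tuple(
        ref_lookup[normalize_symbol(s, gene_set.species)] for s in matched
    )
    return MatchedGeneSet(
        source=gene_set,
        matched=tuple(matched),
        unmatched=tuple(unmatched),
        reference_genes=ref_genes,
    )


def read_gene_list(
    path: str | Path,
    name: str | None = None,
    *,
    species: str = "human",
    normalize: bool = True,
) -> GeneSet:
    """Read a gene list: one symbol per line, or two-column TSV (symbol, p)."""
    path = Path(path)
    symbols: list[str] = []
    pvals: dict[str, float] = {}
    has_p = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\t,]", line)
            sym = parts[0].strip()
            if lineno == 1 and len(parts) >= 2 and parts[0].lower() in ("symbol", "gene"):
                continue
            symbols.append(sym)
            if len(parts) >= 2 and parts[1].strip():
                try:
                    pvals[sym] = float(parts[1])
                    has_p = True
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad p-value {parts[1]!r}") from exc
    return GeneSet.from_symbols(
        name or path.stem,
        symbols,
        provenance=str(path),
        per_gene_p=pvals if has_p else None,
        species=species,
        normalize=normalize,
    )


def read_gmt(path: str | Path, *, species: str = "mouse", normalize: bool = False) -> list[GeneSet]:
    """Read GMT gene sets (``name<TAB>description<TAB>symbol...``).

    Duplicate symbols within a line are deduplicated.  Marker resources such
    as NeuroExpresso use mouse symbols, hence the case-sensitive default.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc, symbols = fields[0], fields[1], fields[2:]
            sets.append(
                GeneSet.from_symbols(
                    name,
                    [s for s in symbols if s.strip()],
                    provenance=desc,
                    species=species,
                    normalize=normalize,
                )
            )
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.provenance or ".", *gs.symbols]) + "\n")
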