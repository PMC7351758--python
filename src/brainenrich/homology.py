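"""Mouse<->human homolog mapping (homologene-style two-column tables)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .atlas import ParseError
from .genesets import GeneSet

__all__ = [
    "read_homolog_map",
    "mouse_to_human",
    "human_to_mouse",
    "translate_symbols",
    "translate_set",
]


def read_homolog_map(path: str | Path, *, delimiter: str | None = None) -> pd.DataFrame:
    """Read a two-column (mouse, human) homolog table.

    A header row is accepted when the columns are named ``mouse``/``human``.
    Duplicate rows are dropped; symbols mapping many-to-many are kept as-is
    (the dictionary builders below keep the first mapping seen).
    """
    sep = delimiter or ("," if str(path).endswith(".csv") else "\t")
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: homolog table needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["mouse", "human"]
    if df.iloc[0].str.lower().tolist() == ["mouse", "human"]:
        df = df.iloc[1:]
    df = df.dropna().apply(lambda c: c.str.strip())
    return df.drop_duplicates(ignore_index=True)


def mouse_to_human(table: pd.DataFrame) -> dict[str, str]:
    out: dict[str, str] = {}
    for m, h in zip(table["mouse"], table["human"]):
        out.setdefault(m, h)
    return out


def human_to_mouse(table: pd.DataFrame) -> dict[str, str]:
    out: dict[str, str] = {}
    for m, h in zip(table["mouse"], table["human"]):
        out.setdefault(h, m)
    return out


def translate_symbols(symbols: Iterable[str], mapping: Mapping[str, str]) -> list[str]:
    """Map symbols through a homolog dictionary, dropping those without a
    homolog and deduplicating while preserving order."""
    seen: dict[str, None] = {}
    for s in symbols:
        t = mapping.get(s)
        if t is not None:
            seen.setdefault(t)
    return list(seen)


def translate_set(
    gene_set: GeneSet, table: pd.DataFrame, direction: str = "mouse_to_human"
) -> GeneSet:
    """Translate a gene set across species via the homolog table."""
    if direction == "mouse_to_human":
        mapping, species = mouse_to_human(table), "human"
    elif direction == "human_to_mouse":
        mapping, species = human_to_mouse(table), "mouse"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return GeneSet.from_symbols(
        gene_set.name,
        translate_symbols(gene_set.symbols, mapping),
        provenance=f"{gene_set.provenance} [{direction}]",
        species=species,
        normalize=(species == "human"),
    )
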