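"""Hypergeometric overlap tests between gene lists and marker sets.

Tests whether two gene sets share more members than expected by chance
within a stated gene universe, with BH-FDR across the cell types of one
marker scan.  Only the upper (enrichment) tail is tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .atlas import ValidationError
from .enrichment import bh_fdr
from .genesets import GeneSet
from .homology import translate_set

__all__ = ["OverlapResult", "hypergeometric_overlap", "marker_scan", "pairwise_overlaps"]


@dataclass(frozen=True)
class OverlapResult:
    """One hypergeometric overlap test (N universe, K marker, n list, k hits)."""

    list_name: str
    marker_name: str
    k_overlap: int
    n_list: int
    K_marker: int
    N_universe: int
    p_raw: float
    p_fdr: float
    overlapping_symbols: tuple[str, ...]


def hypergeometric_overlap(
    list_a: GeneSet | Iterable[str],
    list_b: GeneSet | Iterable[str],
    universe: Iterable[str],
    *,
    name_a: str | None = None,
    name_b: str | None = None,
) -> OverlapResult:
    """Upper-tail hypergeometric P(X >= k) for the overlap of two sets.

    Both sets are intersected with the universe before testing, so the
    margins (n, K) refer to in-universe members only.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    a_name = name_a or getattr(list_a, "name", "list_a")
    b_name = name_b or getattr(list_b, "name", "list_b")
    a = [s for s in getattr(list_a, "symbols", list_a) if s in uni]
    b_set = set(getattr(list_b, "symbols", list_b)) & uni
    hits = tuple(s for s in a if s in b_set)
    N, K, n, k = len(uni), len(b_set), len(a), len(hits)
    if max(n, K) > N:
        raise ValidationError("set larger than universe after intersection")
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    p = min(max(p, 5e-324), 1.0)
    return OverlapResult(
        list_name=a_name, marker_name=b_name, k_overlap=k, n_list=n,
        K_marker=K, N_universe=N, p_raw=p, p_fdr=p, overlapping_symbols=hits,
    )


def _as_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "list": [r.list_name for r in results],
            "marker": [r.marker_name for r in results],
            "k": [r.k_overlap for r in results],
            "n": [r.n_list for r in results],
            "K": [r.K_marker for r in results],
            "N": [r.N_universe for r in results],
            "p": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "genes": [";".join(r.overlapping_symbols) for r in results],
        }
    )


def marker_scan(
    gene_list: GeneSet,
    markers: Sequence[GeneSet],
    universe: Iterable[str],
    *,
    homolog_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test one gene list against every cell-type marker set.

    ``p_fdr`` is BH-adjusted across the marker sets of this scan (the
    number of cell types tested).  When a homolog table is given, marker
    sets are translated mouse->human before testing.
    """
    if not markers:
        raise ValidationError("no marker sets given")
    if homolog_table is not None:
        markers = [translate_set(m, homolog_table, "mouse_to_human") for m in markers]
    results = [
        hypergeometric_overlap(gene_list, m, universe) for m in markers
    ]
    df = _as_frame(results)
    df["p_fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def pairwise_overlaps(
    lists: Sequence[GeneSet], universe: Iterable[str]
) -> pd.DataFrame:
    """All pairwise overlap tests among association gene lists (no FDR)."""
    results = []
    for i in range(len(lists)):
        for j in range(i + 1, len(lists)):
            results.append(hypergeometric_overlap(lists[i], lists[j], universe))
    return _as_frame(results)
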