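"""Synthetic-data generators with planted ground truth.

Emulates every input the pipeline consumes: multi-donor probe-level atlas
bundles with region structure and a planted region-specific gene-set shift,
batched two-condition single-cell matrices with planted directional
effects, gene lists with planted overlaps, marker sets, and a mouse<->human
homolog table.  Atlas noise is additive Gaussian on the (already
normalized) log-intensity scale; single-cell values are zero-inflated
continuous values on a log scale, matching what the rank-based downstream
tests actually consume.  One global seed expands into per-component
substreams so adding a component does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import ProbeExpressionBundle, write_bundle
from .fasting import CellMatrix
from .genesets import GeneSet, write_gmt

__all__ = [
    "AtlasSimSpec",
    "ScSimSpec",
    "simulate_atlas",
    "simulate_sc",
    "simulate_gene_lists",
    "simulate_markers",
    "simulate_homolog_map",
    "write_simulation",
]


@dataclass(frozen=True)
class AtlasSimSpec:
    """Parameters of a synthetic multi-donor atlas.

    The defaults describe the standard evaluation condition: 5,000 genes
    across 40 regions in 3 donors, a 200-gene set shifted upward by
    ``effect`` within-region noise SDs in one planted region.
    """

    n_genes: int = 5000
    n_regions: int = 40
    n_donors: int = 3
    n_samples_per_region: int = 4
    probes_per_gene: int = 1
    planted_set_size: int = 200
    planted_region: str = "region_00"
    effect: float = 2.0
    noise_sd: float = 1.0
    missing_region_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.planted_set_size < self.n_genes):
            raise ValueError("planted_set_size must lie in (0, n_genes)")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.missing_region_rate < 1):
            raise ValueError("missing_region_rate must lie in [0, 1)")
        if self.planted_region not in self.region_names():
            raise ValueError(f"planted_region {self.planted_region!r} not generated")

    def region_names(self) -> list[str]:
        return [f"region_{j:02d}" for j in range(self.n_regions)]

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class ScSimSpec:
    """Parameters of a synthetic batched two-condition single-cell matrix.

    Defaults describe the standard evaluation condition: 3 batches of 150
    cells per arm, 5,000 genes of which 50 are shifted up and 50 down by
    ``log_effect`` in food-deprived cells.
    """

    n_genes: int = 5000
    n_batches: int = 3
    cells_per_arm_per_batch: int = 150
    planted_up: int = 50
    planted_down: int = 50
    log_effect: float = 1.0
    dropout_rate: float = 0.3
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_up + self.planted_down >= self.n_genes:
            raise ValueError("planted_up + planted_down must be < n_genes")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def gene_names(self) -> list[str]:
        return [f"Sim{i:05d}" for i in range(self.n_genes)]


def simulate_atlas(spec: AtlasSimSpec) -> tuple[list[ProbeExpressionBundle], dict]:
    """Generate per-donor probe-level bundles with one planted enriched region.

    Baseline gene means are drawn once and shared across donors; each
    sample's value is gene mean + region intercept + N(0, noise_sd), with
    the planted gene set receiving an extra ``effect * noise_sd`` only in
    the planted region.  Genes expand to ``probes_per_gene`` probe rows
    with small constant probe offsets.  A ``missing_region_rate`` fraction
    of (donor, region) blocks is omitted to emulate incomplete coverage.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + spec.n_donors)
    rng_global = np.random.default_rng(children[0])
    rng_missing = np.random.default_rng(children[1])

    genes = spec.gene_names()
    regions = spec.region_names()
    baseline = rng_global.normal(8.0, 2.0, spec.n_genes)
    region_intercept = rng_global.normal(0.0, 0.5, spec.n_regions)
    planted_idx = rng_global.choice(spec.n_genes, spec.planted_set_size, replace=False)
    planted_genes = [genes[i] for i in sorted(planted_idx)]
    planted_mask = np.zeros(spec.n_genes, dtype=bool)
    planted_mask[planted_idx] = True
    probe_offsets = rng_global.normal(0.0, 0.1, (spec.n_genes, spec.probes_per_gene))

    drop = rng_missing.random((spec.n_donors, spec.n_regions)) < spec.missing_region_rate
    # every region must survive in at least one donor
    for j in range(spec.n_regions):
        if drop[:, j].all():
            drop[0, j] = False

    bundles = []
    planted_col = regions.index(spec.planted_region)
    for d in range(spec.n_donors):
        rng = np.random.default_rng(children[2 + d])
        cols: dict[str, np.ndarray] = {}
        sample_region: dict[str, str] = {}
        for j, region in enumerate(regions):
            noise = rng.normal(0.0, spec.noise_sd,
                               (spec.n_genes, spec.n_samples_per_region))
            if drop[d, j]:
                continue
            vals = baseline[:, None] + region_intercept[j] + noise
            if j == planted_col:
                vals[planted_mask] += spec.effect * spec.noise_sd
            for k in range(spec.n_samples_per_region):
                sid = f"d{d}_{region}_s{k}"
                cols[sid] = vals[:, k]
                sample_region[sid] = region
        gene_block = pd.DataFrame(cols, index=genes)
        probe_rows, probe_ids, probe_gene = [], [], {}
        for p in range(spec.probes_per_gene):
            block = gene_block.add(probe_offsets[:, p], axis=0)
            block.index = [f"{g}_p{p}" for g in genes]
            probe_rows.append(block)
            for g in genes:
                probe_gene[f"{g}_p{p}"] = g
        expression = pd.concat(probe_rows, axis=0)
        bundles.append(
            ProbeExpressionBundle(
                donor_id=f"donor{d}",
                expression=expression,
                sample_region=sample_region,
                probe_gene=probe_gene,
            ).validate()
        )
    truth = {
        "planted_genes": planted_genes,
        "planted_region": spec.planted_region,
        "effect": spec.effect,
        "spec": asdict(spec),
    }
    return bundles, truth


def simulate_sc(spec: ScSimSpec) -> tuple[CellMatrix, dict]:
    """Generate a batched two-condition single-cell matrix with planted DE.

    Per-gene baseline log-means come from a lognormal-style prior; deprived
    cells' means are shifted by +/- ``log_effect`` for planted genes.
    Values are max(0, mean + Gaussian noise) with zero-inflation at
    ``dropout_rate`` and batch-specific intercepts.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(1 + spec.n_batches)
    rng = np.random.default_rng(children[0])
    genes = spec.gene_names()
    base = rng.lognormal(mean=0.0, sigma=0.6, size=spec.n_genes)
    picked = rng.choice(spec.n_genes, spec.planted_up + spec.planted_down, replace=False)
    up_idx, down_idx = picked[: spec.planted_up], picked[spec.planted_up:]
    shift = np.zeros(spec.n_genes)
    shift[up_idx] = spec.log_effect
    shift[down_idx] = -spec.log_effect

    cols: dict[str, np.ndarray] = {}
    condition: dict[str, str] = {}
    batch_label: dict[str, str] = {}
    sex: dict[str, str] = {}
    for b in range(spec.n_batches):
        rng_b = np.random.default_rng(children[1 + b])
        intercept = rng_b.normal(0.0, 0.3)
        for cond in ("fed", "deprived"):
            mean = base + intercept + (shift if cond == "deprived" else 0.0)
            n = spec.cells_per_arm_per_batch
            vals = mean[:, None] + rng_b.normal(0.0, spec.dispersion, (spec.n_genes, n))
            vals = np.clip(vals, 0.0, None)
            if spec.dropout_rate > 0:
                vals[rng_b.random(vals.shape) < spec.dropout_rate] = 0.0
            for k in range(n):
                cid = f"b{b}_{cond}_{k}"
                cols[cid] = vals[:, k]
                condition[cid] = cond
                batch_label[cid] = str(b)
                sex[cid] = "F"
    values = pd.DataFrame(cols, index=genes)
    cm = CellMatrix(
        values=values,
        condition=pd.Series(condition),
        batch=pd.Series(batch_label),
        sex=pd.Series(sex),
        name=f"sim_sc_seed{spec.seed}",
    ).validate()
    truth = {
        "up": [genes[i] for i in sorted(up_idx)],
        "down": [genes[i] for i in sorted(down_idx)],
        "log_effect": spec.log_effect,
        "spec": asdict(spec),
    }
    return cm, truth


def simulate_gene_lists(
    universe_size: int,
    list_sizes: Sequence[int],
    planted_overlap: int,
    seed: int = 0,
) -> tuple[list[GeneSet], dict]:
    """Draw gene lists from a shared universe with a planted exact overlap.

    The first list shares exactly ``planted_overlap`` symbols with the
    second; any further lists are drawn disjointly from the remaining pool.
    """
    if planted_overlap > min(list_sizes[:2] if len(list_sizes) > 1 else list_sizes):
        raise ValueError("planted_overlap exceeds a list size")
    if sum(list_sizes) - planted_overlap > universe_size:
        raise ValueError("universe too small for the requested lists")
    rng = np.random.default_rng(seed)
    universe = [f"U{i:06d}" for i in range(universe_size)]
    order = rng.permutation(universe_size)
    lists: list[GeneSet] = []
    pos = 0
    shared = [universe[i] for i in order[:planted_overlap]] if len(list_sizes) > 1 else []
    pos = len(shared)
    for li, size in enumerate(list_sizes):
        if li < 2 and shared:
            own = size - len(shared)
            symbols = shared + [universe[i] for i in order[pos: pos + own]]
            pos += own
        else:
            symbols = [universe[i] for i in order[pos: pos + size]]
            pos += size
        lists.append(GeneSet.from_symbols(f"list_{li}", symbols, normalize=False))
    truth = {"universe": universe, "planted_overlap": planted_overlap}
    return lists, truth


def simulate_markers(
    universe: Sequence[str],
    n_sets: int = 5,
    set_size: int = 100,
    *,
    planted_list: GeneSet | None = None,
    planted_shared: int = 0,
    seed: int = 0,
) -> list[GeneSet]:
    """Random marker sets; one set optionally shares ``planted_shared``
    symbols with a given gene list."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    set_size = min(set_size, len(universe))
    sets = []
    for i in range(n_sets):
        picks = list(rng.choice(len(universe), set_size, replace=False))
        symbols = [universe[j] for j in picks]
        if i == 0 and planted_list is not None and planted_shared > 0:
            inject = list(planted_list.symbols[:planted_shared])
            symbols = inject + [s for s in symbols if s not in set(inject)][: set_size - len(inject)]
        sets.append(GeneSet.from_symbols(f"celltype_{i}", symbols, normalize=False))
    return sets


def simulate_homolog_map(mouse_genes: Sequence[str], *, drop_fraction: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Mouse->human table mapping each mouse symbol to its upper-cased form,
    optionally dropping a fraction to emulate genes without homologs."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(mouse_genes)) >= drop_fraction
    rows = [(g, g.upper()) for g, k in zip(mouse_genes, keep) if k]
    return pd.DataFrame(rows, columns=["mouse", "human"])


def write_simulation(outdir: str | Path, *, seed: int = 0,
                     atlas_spec: AtlasSimSpec | None = None,
                     sc_spec: ScSimSpec | None = None) -> dict:
    """Write a complete simulated input bundle directory.

    Produces per-donor atlas CSVs, gene-list files, a marker GMT, dense
    single-cell TSVs with metadata, a homolog table and a truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    atlas_spec = atlas_spec or AtlasSimSpec(seed=seeds[0])
    sc_spec = sc_spec or ScSimSpec(seed=seeds[1])

    bundles, atlas_truth = simulate_atlas(atlas_spec)
    donor_paths = {}
    for b in bundles:
        paths = write_bundle(b, outdir / b.donor_id)
        donor_paths[b.donor_id] = {k: str(v) for k, v in paths.items()}

    planted = atlas_truth["planted_genes"]
    with open(outdir / "planted_list.txt", "w") as fh:
        fh.write("\n".join(planted) + "\n")
    rng = np.random.default_rng(seeds[2])
    others = sorted(set(atlas_spec.gene_names()) - set(planted))
    random_list = [others[i] for i in rng.choice(len(others), min(200, len(others)), replace=False)]
    with open(outdir / "random_list.txt", "w") as fh:
        fh.write("\n".join(sorted(random_list)) + "\n")

    marker_size = min(100, max(5, atlas_spec.n_genes // 4))
    markers = simulate_markers(
        atlas_spec.gene_names(), set_size=marker_size,
        planted_list=GeneSet.from_symbols("planted", planted),
        planted_shared=min(20, marker_size // 2, len(planted)), seed=seeds[3],
    )
    write_gmt(markers, outdir / "markers.gmt")

    cm, sc_truth = simulate_sc(sc_spec)
    cm.values.to_csv(outdir / "sc_expression.tsv", sep="\t", index_label="gene")
    meta = pd.DataFrame(
        {"cell": cm.values.columns,
         "condition": cm.condition.loc[cm.values.columns].to_numpy(),
         "batch": cm.batch.loc[cm.values.columns].to_numpy(),
         "sex": cm.sex.loc[cm.values.columns].to_numpy()}
    )
    meta.to_csv(outdir / "sc_metadata.tsv", sep="\t", index=False)
    homologs = simulate_homolog_map(sc_spec.gene_names())
    homologs.to_csv(outdir / "homologs.tsv", sep="\t", index=False, header=False)

    truth = {"atlas": atlas_truth, "sc": sc_truth, "seed": seed}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
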