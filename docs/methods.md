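# Methods

## Reference matrix construction

The substrate for all regional tests is a gene×region matrix of
donor-averaged, z-scored within-region expression ranks. Per donor the
stages are fixed as: probe→gene mean collapse, sample→region mean
averaging, within-region midranking, across-region z-scoring, then a
cell-wise mean across donors. Ranking before z-scoring is deliberate: the
rank step removes region-specific distributional shape (dissection and
hybridization differences between regions), and the z step then expresses
each gene's regional profile relative to its own brain-wide level. The
order is fixed per donor (rank → z → donor mean) and asserted by stage
tags on the matrix object.

Conventions and numerical choices:

- **Ties** receive midranks (average of the tied positions), the same
  convention the downstream Mann–Whitney statistic assumes. A tie-free
  column's ranks are exactly a permutation of 1..n.
- **Z-scores** use the sample (n−1) standard deviation. Rows observed in
  fewer than two regions become all-missing and are flagged; zero-variance
  rows become all-zero (neutral) rather than being dropped, which keeps
  the gene vocabulary stable for set matching.
- **Missing values** propagate: they are excluded from probe means,
  regional means, and reduce n for ranks and z-scores. Donor averaging
  takes each cell's mean over the donors that observed it (fetal-style
  atlases do not cover every region in every donor); the per-cell donor
  count is carried as a sidecar matrix.
- **Composite regions** (e.g. merging several dissection labels into one
  subgenual-cingulate profile) pool all member-region *samples* before
  averaging, so members with more samples weigh more. The alternative
  (mean of member means) is available as `pool_samples=False`.
  Hemisphere-duplicated regions carry identical names and therefore pool
  automatically.
- Region-name matching is exact byte comparison after whitespace
  trimming; annotation column names are configurable with Allen-layout
  defaults.

## AUROC enrichment statistic

For a region r and matched gene set S, scores are the reference z-values
of all genes observed in r, converted to midranks. With rank sum R_S over
the set genes,

    U = R_S − n_S(n_S+1)/2,    AUROC = U / (n_S · n_B),

the probability that a random set gene out-ranks a random background gene,
tied pairs counting one half. AUROC > 0.5 indicates regionally specific
(enriched) expression, < 0.5 depletion.

Significance is two-sided by default (direction read from the AUROC), with
one-sided alternatives available. The null is handled two ways:

- **Exact** (combined n ≤ 20, tie-free): the full null distribution of U
  is computed by a rank-sum counting recurrence, equivalent to enumerating
  all C(n, n_S) labelings; the two-sided p is twice the smaller tail,
  capped at 1. This covers the half-dozen-gene locus lists where the
  normal approximation is poorest.
- **Approximate** (larger n or ties): normal approximation with
  tie-corrected variance
  var = n_S n_B/12 · [(n+1) − Σ(t³−t)/(n(n−1))] and a 0.5 continuity
  correction. Exhaustively over every achievable U at combined n = 12 the
  approximation stays within 0.02 of exact for splits with ≥ 4 per group;
  for extreme splits (1 or 2 set genes) its worst-case error is inherently
  larger, which is precisely why the exact path owns that regime.

Per reference matrix, p-values are Benjamini–Hochberg adjusted across all
regions (statsmodels step-up), and regions receive a brain-wide rank by
descending AUROC with ties broken by ascending region name so outputs are
deterministic. Set genes missing in a region are excluded from that
region's test, with per-region n recorded.

Small matched sets (default threshold 20, configurable) are reported in
regions-of-interest mode — uncorrected p plus the brain-wide rank from the
full run — because the power of the AUROC test is driven by set size and
brain-wide FDR claims from tiny sets are not meaningful. ROI names absent
from a reference are reported as `not_profiled`, not errors.

## Gene lists, symbol handling, overlaps

Human symbols are upper-cased and one trailing `-AS<digits>` or
`-IT<digits>` suffix is stripped, mapping antisense/intronic transcripts
onto their host gene. The rule is applied once, not recursively; repeated
application is a no-op for all realistic symbols (stacked suffixes like
`X-AS1-AS1` do not occur in nomenclature). Mouse symbols are
case-sensitive and untouched; cross-species tests go through an explicit
homologene-style two-column mouse↔human table (first mapping wins for
many-to-many symbols).

Exome-derived lists with per-gene p-values are reduced by a Bonferroni
filter: keep genes with p·m ≤ α (inclusive boundary), m defaulting to a
20,000-gene genome estimate, α = 0.05.

Overlap tests are upper-tail hypergeometric: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), both sets intersected with the stated universe
first. In marker scans the FDR is taken over the cell types tested in that
scan. The universe is an explicit argument everywhere; by default the
pipeline uses the reference matrix's gene vocabulary. The universe choice
materially moves these p-values, so reproductions must state it.

## Single-cell fasting differential expression

Each (dataset, batch) pair is one stratum; every retained stratum must
contain cells of both conditions. Per stratum and gene, a Mann–Whitney
test compares food-deprived to fed cells; `p_up` and `p_down` are the two
one-sided, tie- and continuity-corrected tails of the same U (computed via
scipy's vectorised asymptotic path — stratum arm sizes in the hundreds
make the exact path unnecessary). Because the test is rank-based, any
monotone expression scale (log-TPM, ln-CPM) is valid input as-is.

Per direction, the stratum p-values are combined with Fisher's method,
X² = −2Σ ln p against chi-square with df = 2k, p clamped at 1e-300 before
the log. Genes missing in a stratum contribute only their available strata
(df = 2·available). BH-FDR is applied per direction across all tested
genes (the joint-correction alternative is a one-line change and noted as
configurable); a gene's direction call is the smaller-FDR direction when
that FDR is below α, else `none`. Gene-level filters before testing:
must have a human homolog, nonzero expression in ≥ 1 cell, nonzero
variance across cells.

The summary step reports the genome-wide DE fraction, each list's DE
fraction among its genes with data, and an upper-tail hypergeometric p for
whether a list is disproportionately DE.

## Synthetic data

The generators produce what the pipeline consumes, not raw measurements:

- **Atlas**: additive Gaussian noise on a log-intensity-like scale
  (baseline gene means N(8, 2), region intercepts N(0, 0.5), noise SD 1),
  because real atlas inputs arrive already normalized. The planted set is
  shifted by `effect`·noise-SD in one region only. Defaults — 5,000 genes,
  40 regions, 3 donors, 4 samples/region, 200 planted genes, effect 2 —
  are the package's standard evaluation condition, sized so a desk-scale
  run exercises the same statistical regime (thousands of background
  genes, tens of regions, few donors) as a full atlas.
- **Single cell**: zero-inflated continuous values on a log scale
  (lognormal(0, 0.6) baseline means, batch intercepts N(0, 0.3), noise SD
  0.5, dropout 0.3), again because downstream testing is rank-based.
  Defaults: 3 batches × 150 cells/arm, 5,000 genes, 50 up + 50 down
  planted at one log-unit.
- **Gene lists / markers / homologs**: exact planted overlaps; homolog
  table maps mouse symbols to their upper-cased form with an optional
  dropped fraction.

One global seed expands into per-component `SeedSequence` substreams, so
all generators are byte-deterministic and adding a component does not
perturb the others. What passing tests on these inputs do **not** show:
robustness to correlated region covariance, spatial autocorrelation,
UMI-level count noise, batch-confounded condition effects, or annotation
errors — none of which the generators emulate.

## Known limitations

- Probe re-annotation is out of scope; the probe→gene map is taken as
  given, so results inherit its quality.
- The AUROC test treats genes as independent; co-expressed sets inflate
  significance, which is why planted-signal recovery (not p calibration on
  correlated sets) is the headline validation.
- No conditional or competitive marker enrichment; overlaps are marginal
  hypergeometric tests.
- Mouse fasting responses are a physiological probe, not a disease model;
  the DE module makes no causal claims.
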