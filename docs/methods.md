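# Methods

This note documents the models, defaults and design choices behind `ctsr`,
in the order the pipeline runs them, plus what the synthetic generator
does and does not emulate.

## Preprocessing

Genes are kept when detected (nonzero) in at least `gene_min_cell_fraction`
of cells (default 0.001, so a gene nonzero in exactly 0.1% of cells is
kept); cells are kept with at least `cell_min_genes` detected genes
(default 200). The gene filter runs first, then the cell filter, in a
single pass; the gene filter is not recomputed after cell removal.
Normalization state is auto-detected: a matrix whose nonzero entries are
all integers (tolerance 1e-9, so counts stored as floats still count) is
treated as raw. Raw counts are scaled per cell by library size divided by
the median library size. This is a deliberate simplification of pooled
deconvolution size factors: the downstream activity score uses only
within-cell ranks, which are invariant to any per-cell scale factor, so
the choice of size-factor scheme cannot change regulon calls — it only
affects the reported DEG fold changes, mildly. Both paths end with
log(x+1).

## Biclustering

Qualitative biclustering in the QUBIC style, fully specified and
deterministic:

- **Discretization** (`q`, default 0.06): per gene, the top ⌈q·n⌉ cells by
  value become +1 and the bottom ⌈q·n⌉ become −1, with three guards: raw
  zeros never become +1, constant genes stay all-zero, and boundary ties
  resolve by ascending cell index. If q·n < 1, q is raised to 1/n with a
  warning.
- **Seeding**: gene pairs weighted by the number of cells sharing the same
  nonzero level; pairs with weight < 2 are dropped; order is weight
  descending, then lexicographic gene ids.
- **Expansion** (`consistency` c, default 0.95): starting from the seed
  pair's agreeing cells (cells₀), the gene keeping the most cells is added
  greedily; adding a gene restricts the cell set to cells where it carries
  the shared level, and an addition is accepted only while at least
  max(2, ⌈c·|cells₀|⌉) cells survive. Returned blocks are therefore pure
  constant-level submatrices that retain ≥ c of the seed's cells; c = 1
  demands perfect blocks, c = 0.95 tolerates sporadic corrupted entries.
- **Filtering**: a candidate block is discarded when its gene-set Jaccard
  overlap with an already-kept block is ≥ `overlap_filter` (default 0.75);
  the search stops at `max_biclusters` (default 500; 100 in fast mode).
  Only up-regulated (+1) blocks feed module assignment by default, since
  regulons are sought among actively expressed genes; −1 blocks can be
  enabled.

This replaces a mixture-model discretizer and divergence-based expansion
with a quantile discretizer and count-based expansion: the variant is
deterministic, has an exactly checkable output invariant, and recovers
planted blocks verifiably against a brute-force maximal-block oracle.

## Module assignment

Every (bicluster, cell type) pair gets an upper-tail hypergeometric test
of the bicluster's cells against the type's cells. Adjustment is
Bonferroni with the global multiplier N_cell_types × N_biclusters (all
biclusters entering the stage, not only significant ones); pairs with
adjusted p < 0.05 become modules. One bicluster may be a module of several
types; the smallest-raw-p pair per bicluster is flagged as its best
assignment. At alpha = 1 every pair is emitted (useful for calibration
studies). Because the test statistic is discrete, raw p-values are
conservative: P(p < t) ≤ t with equality only at achievable tail points.
The calibration test in the suite uses 250 cells in 5 equal types and
30-cell biclusters, a design where the achievable level closest to 0.05
is 0.0494, so nominal and achievable levels agree.

## Promoters and motif scanning

Promoters are the `promoter_len` (default 1000) bases immediately upstream
of the TSS: [max(1, tss−L), tss−1] for + genes, [tss+1, tss+L]
reverse-complemented for − genes, clipped at chromosome ends, N bases
preserved. Internally coordinates are 1-based closed; the BED export is
0-based half-open.

PWMs are scored as log2 odds against a background (uniform 0.25 by
default) with pseudocount 1e-4, scaled to integers at 1/1000 bit. The
exact distribution of window scores under the background is computed by
per-position convolution (verified against full 4^w enumeration); the scan
threshold is the smallest score with tail probability ≤ `scan_alpha`
(default 1e-4). Both strands are scanned; reverse-strand matches are
reported at forward coordinates; windows containing non-ACGT bases are
skipped. Per cell type, module genes with ≥ 1 hit for a TF's motif form
the TF's regulon; motifs sharing a TF name merge by gene union; regulons
need ≥ `min_regulon_genes` (default 5) genes to avoid degenerate one-gene
regulons. Scanning a known-PWM library stands in for de novo motif
discovery plus motif-database matching; the scan p-value threshold plays
the role of the downstream motif significance filter.

## Regulon scoring

- **RAS**: with K = ⌈top_fraction · n_genes⌉ (top_fraction default 0.05)
  and per-cell descending ranks (ties by gene index), the recovery curve
  counts regulon genes among the top k for k = 1..K; RAS is the curve's
  sum divided by its maximum for that regulon size, hence in [0, 1] and
  purely rank-based (invariant to any per-cell monotone transform).
- **RSS** = 1 − √JSD(p, q) with p the RAS vector normalized over cells and
  q the normalized cell-type indicator, base-2 logs. RSS = 1 iff the
  normalized activity equals the indicator; RSS = 0 on disjoint support.
  An all-zero RAS vector is defined as RSS 0 with a warning.
- **Bootstrap p**: `n_boot` (default 10 000) gene sets of the regulon's
  size drawn uniformly *without replacement* (a "bootstrap" with repeats
  would make gene sets degenerate); p = (1 + #{RSS_null ≥ RSS_obs}) /
  (1 + n_boot), which never returns 0. Null RSS values within 1e-12 of the
  observed count as ties in its favor, keeping p conservative.
- **Calls**: per cell type, p is Bonferroni-multiplied by the number of
  regulons in that type; CTSR iff adjusted p < alpha (0.001/0.01/0.05,
  default 0.05). Names are CT{n}-R{m}: n indexes cell types in label
  order, m ranks by ascending empirical p, ties by descending RSS then TF
  name.

Every stochastic step derives its RNG stream from the run seed (one
spawned substream per regulon), so results are bit-reproducible.

## Synthetic data generator

Baseline counts are negative binomial with mean 2 and dispersion 0.5 in
the variance function var = μ + 0.5·μ² (shape r = 2) — typical magnitudes
for moderately sequenced scRNA-seq. Cells split into contiguous
near-equal cell-type blocks. Each planted regulon is a disjoint random
gene set whose NB mean is multiplied by `fold_change` in its cell type
before sampling; dropout then zeroes entries independently (default 0.3).
Each gene gets its own chromosome: a uniform-ACGT promoter of
`promoter_len` plus a short gene body, with the regulon's TF consensus
(12 bp, drawn uniformly) pasted at a uniform random offset in every target
promoter; the motif library holds one PWM per TF with 0.85 probability on
the consensus base per position. Consensus pasting (rather than sampling
from the PWM) keeps recall accounting unambiguous.

What the generator does **not** emulate: gene–gene correlation beyond the
planted type effect, batch effects, doublets, UMI saturation, realistic
promoter composition or motif clustering, overlapping regulons. Passing
the planted-recovery tests therefore shows the machinery is correct and
calibrated under the stated model, not that real-data performance matches
any published benchmark.

## Problem sizes used in tests and the acceptance script

The flagship regression uses the generator defaults — 2000 genes × 600
cells × 3 types, three 30-gene regulons, fold change 4, dropout 0.3 — the
smallest configuration where the default discretization quantile
(0.06 × 600 = 36 marked cells per gene) yields module-level enrichment
comfortably clearing the global Bonferroni correction. The negative
control reruns it with fold change 1 at alpha 0.001 across ten seeds.
Calibration tests use 250–500 cells and n_boot = 500 for the bootstrap
uniformity check (200 trials, KS < 0.1).

## Known limitations

- The per-cell-scale size factors diverge from pooled-deconvolution
  normalization; fold changes (not regulon calls) depend on this choice.
- The bicluster expansion is greedy; it recovers planted constant-level
  blocks exactly but has no optimality guarantee on arbitrary matrices.
- The hypergeometric multiplier counts all tested biclusters, which is
  conservative when many near-duplicate biclusters are kept.
- A user-supplied gene-module file carries no cell sets, so its columns
  are taken as cell-type-labeled modules directly and skip the enrichment
  stage entirely.
- Gene identifiers are opaque strings; no symbol/ID translation is
  performed, and hdf5 feature-barcode input is not supported.
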