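# Methods

`radlayers` re-implements, as a tested and reusable pipeline, a spatial
analysis of radiation-induced DNA methylation: which CpG probes change
after exposure to high-LET particles (iron, silicon ions) versus low-LET
X-rays, whether those changes cluster into genomic regions, how they
distribute across radial layers of the cell nucleus derived from Hi-C
scores, how histone-mark context modulates them, and whether the
persistence contrast (iron: durable; silicon/X-ray: transient) replays at
the gene-expression level. All analyses run end-to-end on synthetic data
with planted ground truth; the package never requires the original array,
Hi-C or ChIP-seq accessions.

## Differential methylation

Beta values (methylated / total intensity, in (0,1)) are transformed to
M values, `M = log2(beta / (1 - beta))`; boundary values of exactly 0 or 1
are clamped to ±1e-6 with a warning. All effect thresholds operate on the
M scale, where array noise is closest to homoscedastic.

Per probe, the two compared groups (e.g. Fe 1 Gy vs Si 1 Gy at 48 h) are
tested with a one-way two-group ANOVA on M values — the F statistic equals
the squared pooled-variance t, with the F(1, n_a+n_b−2) reference
distribution. q-values are Benjamini–Hochberg (deterministic; a density-
estimating q-value procedure is a possible extension, not implemented).
The control level of each probe is the mean M across *all* non-irradiated
(dose 0) samples pooled over particle batches, since those batches share
culture, collection time and baseline methylation. A probe passes when

* q < 0.05, and
* |avDiff| ≥ 0.58 (mean M difference between the compared groups), and
* |Δ vs control| ≥ 0.58 (focal-group mean M minus control mean M).

The filter order is immaterial to the final set. The focal ("group A")
condition is always the first-named particle of a comparison, so `av_diff`
and `delta_vs_control` are signed from its point of view. Passing probes
get a baseline state (hypo if control M < 0, hyper otherwise; an exact 0
counts as hyper and is flagged) and a direction (up/down by the sign of
Δ vs control). Missing values are excluded pairwise — never imputed — in
every mean and test.

Degenerate probes (zero within-group variance in both groups) are flagged;
p is 0 if the group means differ and 1 if they coincide.

## DMR grouping

Passing probes are chained per chromosome while the gap between
consecutive probes is ≤ λ (default 1000 bp); chains with ≥ 2 probes become
differentially methylated regions spanning first to last probe. This
distance-chaining semantics replaces kernel-smoothing DMR callers: the
pipeline uses DMRs only to count probes inside versus outside regions and
to probe sensitivity to the base-pair limit, for which max-gap chaining is
the direct formalisation. Each region reports its member probes and the
unweighted mean of their Δ vs control. The headline statistic is the
*fraction of passing probes inside DMRs*.

## Permutation null for clustering

To ask whether differential probes cluster in the genome more than chance
allows, probe ids are randomly re-assigned to methylation value rows
(coordinates decoupled from values; the multiset of rows unchanged) and
the whole calling + DMR pipeline is repeated B times (default 1000; 200 in
fast mode). The empirical p uses the add-one rule
`p = (1 + #{null ≥ observed}) / (B + 1)`, tail "greater" (clustered truth
should exceed scattered nulls), and is never exactly 0. Implementation
note: every per-row statistic is invariant under id relabelling, so the
passing row set is computed once and only the id→coordinate map is redrawn
per replicate — mathematically identical to rerunning the full pipeline,
at a fraction of the cost. A permuted replicate with zero passing probes
contributes fraction 0 and is logged.

## Radial nuclear layers

Each probe inherits the score of the Hi-C bin containing its position
(bins validated non-overlapping; the half-open convention puts a probe at
a bin's `end` into the next bin; uncovered probes are dropped from spatial
analyses and counted). Probes are ranked by the stable key (score, chrom,
position) and cut into five contiguous equal-occupancy blocks — L1 the
lowest scores (nuclear periphery) to L5 the highest (interior), occupancy
differing by at most 1 even under score ties. Equal occupancy by rank is
the defining property ("each layer holds the same amount of DNA");
score-value quantiles, which break under ties, are reported only as the
descriptive layer boundaries (empirical 0/20/40/60/80/100% quantiles).

Layer summaries: percent of DMPs per layer (sums to 100, with the same
profile over non-DMP probes as reference), per-chromosome DMP frequency
normalised by the chromosome's probe count (removes array-design bias),
the chromosome × layer frequency matrix (cells without probes are NaN,
never 0), and the per-layer mean |Δ vs control|.

## Histone marks and regulatory regions

Peak sets (H3K4me3, H3K27ac, H3K27me3, H3K9me3) are filtered to lengths in
[300, 2000] bp and an alignment-score rule configurable per source
(`score ≥ 10` or `score > 0`, mirroring the two source pipelines). A probe
carries a mark when its point lies in ≥ 1 filtered peak; point-in-region
queries run by binary search on merged sorted intervals and are verified
against a quadratic scan in the tests.

The enrichment read-out is the DMP-occurrence probability ratio per layer:

    (DMPs in-region in-layer / all DMPs) /
    (region probes in-layer / all region probes)

1.0 means no enrichment; undefined cells (zero denominators) are NaN. The
ratios satisfy the weighted-average identity (Σ over layers of ratio ×
layer-region-fraction = overall DMP-in-region fraction), which the tests
assert.

Five regulatory classes are built from TSS windows (± 2000 bp by default —
the shore-distance scale; configurable) and the filtered H3K4me3/H3K27ac
peaks: promoters with K4 only, K27ac only, both, neither (a partition of
the TSS set; overlap = ≥ 1 shared bp), plus K27ac enhancers having zero
overlap with any TSS window or gene body. Per class and layer the pipeline
reports mean |Δ vs control| and mean baseline M with member counts.

## Expression validation

RNA-seq counts are normalised with TMM (trimmed mean of M-values):
reference = sample whose upper quartile of count/library-size is closest
to the mean upper quartile; gene-wise log2 ratios vs the reference are
rank-trimmed (30% on M, 5% on abundance) and combined with
inverse-variance (delta-method binomial) weights; factors are scaled to
geometric mean 1. The implementation agrees with the Bioconductor
reference to ~1e-12 (cross-checked in the tests). log-CPM uses a 0.5
pseudo-count over TMM-effective library sizes. Microarray data arrive
normalised and are filtered to genes with median intensity ≥ 3; the
single-replicate astronaut series is folded into five groups of two
pseudo-replicates by a configurable pairing map (shipped default: control
= two pre-flight, two in-flight groups, two post-flight groups).

The first-timepoint gate tests each gene against control with a
pooled-variance t-test whose gene variances are squeezed toward a fitted
scaled-inverse-chi-square prior (moment estimator on log s²; the test uses
df + d0 degrees of freedom). This empirical-Bayes moderation is the
package's design choice: with 3 vs 3 replicates a raw df-4 t-test has too
little power for any FDR-gated recovery, while moderation keeps null
p-values uniform (KS-checked in the tests) and is the standard practice
for few-replicate designs. BH (default) or Bonferroni adjustment; gate =
FDR < 0.05. Gated genes get logFC trajectories vs control at every
timepoint, an up/down class from the first-timepoint sign, per-class mean
trajectories, and trend tests (slope ANOVA always; Mann–Kendall when ≥ 4
timepoints). Genes are mapped into nuclear layers by their TSS's Hi-C bin
score against the probe-derived layer boundaries.

A negative-binomial GLM on counts is an extension point, not implemented:
this module validates persistence trends, not count-model equivalence.

## Statistics

* Mann–Kendall: S = Σ_{i<j} sign(x_j − x_i); exact p for tie-free series
  with n ≤ 9 from the inversion-count (Mahonian) null distribution,
  normal approximation with continuity and tie correction otherwise;
  refuses n < 4. The exact branch is verified exhaustively against full
  permutation enumeration for n ≤ 7.
* Chi-squared: Pearson statistic without continuity correction,
  df = (r−1)(c−1); all expected counts must be positive.
* Slope ANOVA: OLS slope with the regression-ANOVA F test of slope = 0;
  constant y gives F = 0, p = 1.
* BH adjustment: `q_i = min_{j ≥ rank(i)} m p_(j) / j` capped at 1,
  monotone in p; NaN inputs propagate without counting toward m.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions, chosen once:

* **Scale**: 20,000 probes on 4 chromosomes of 25 Mb — a desk-scale
  stand-in for a 485k-probe array; 3 replicates per condition.
* **Manifest**: ~30% of probes sit inside generated CpG islands (1 kb
  wide, 5 probes each — the dense clusters methylation arrays actually
  have, and the raw material for DMR formation), the rest uniform. CpG
  relation is assigned from distance to the nearest island (0 inside;
  ≤ 2 kb shore; ≤ 4 kb shelf; open sea beyond; boundaries inclusive on
  the nearer class) and genic group from generated TSS/gene-body
  intervals (promoter ±2 kb of TSS > body > upstream/downstream ≤ 10 kb >
  intergenic).
* **Hi-C track**: 100 kb bins tiling each chromosome; per-chromosome mean
  shifts spread over ±1 plus unit Gaussian bin noise, giving chromosomes
  distinct radial preferences.
* **Methylation**: baseline Beta from a bimodal mixture (Beta(2,18) /
  Beta(18,2): hypo mode near 0.1, hyper near 0.9), shared across samples;
  replicate noise Gaussian on the M scale, sd 0.15. Particles: iron
  (+1.5 M, persistent), silicon (−1.5 M, decaying ×0.5 per timepoint),
  X-ray (−1.0 M, decaying), each at 5% of probes; planted Δ is scaled by
  the probe's layer weight, default profile (0.5, 0.8, 1.0, 0.8, 0.6)
  to mimic the mid-nucleus L3 peak (set flat for null experiments). Half
  of each particle's true probes are drawn as whole island clusters
  (≤ 1 kb span) so that region-building has signal — mirroring the
  observation that roughly half of differential probes form regions —
  the rest uniformly.
* **Peaks**: widths uniform in [300, 2000] bp with alignment scores
  uniform in [0, 50]; bin placement probability decreases with the bin's
  score percentile for H3K9me3 (peripheral heterochromatin), increases
  for H3K27ac, flat for the others.
* **Counts**: negative-binomial (dispersion 0.1), gene means lognormal,
  library sizes ×U[0.5, 2]; 5% of genes get |logFC| = 2 at the first of
  four timepoints, alternating up/down and persistent/decaying (×0.5 per
  timepoint).

Every stage draws from an independent deterministic stream derived from
the single mandatory seed, so identical config + seed reproduce outputs
byte-for-byte regardless of call order.

What the generator does **not** emulate: probe-type (Infinium I/II)
chemistry, cross-reactive probes, batch effects, genuine Hi-C contact
structure (scores are drawn, not computed from matrices), ChIP-seq signal
shape, or dose–response curves. Passing tests therefore demonstrate that
the pipeline's logic recovers the structures it assumes — not that those
structures are correctly estimated from raw real-world data.

## Problem sizes used in the checks

The bundled acceptance script and tests run at 10,000–20,000 probes, 200
permutations (fast mode), 20 seeds per stochastic claim and 3,000–5,000
genes — sizes chosen so every recovery signal is far from its threshold
while a full run stays in the minutes range on one core.

## Known limitations

* The DMR builder is max-gap chaining; kernel-based callers can merge or
  split differently near the bandwidth scale.
* BH is used where a q-value estimator was conceivable; with many true
  effects BH is slightly conservative.
* The Hi-C score is taken as given input; which upstream quantity it is
  (compartment eigenvector or otherwise) is outside the package.
* Layer quantiles are computed over probes (the equal-DNA reading), not
  over genomic bins.
* The astronaut pairing is config data, not logic; other missions need
  their own map.
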