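# Methods

This note documents the statistical models, the numerical choices, and the
limits of the synthetic data on which the package is exercised.

## Differential testing: a deliberate stand-in

Counts are modelled per feature as negative binomial with the DESeq-style
parameterization Var = μ + α·μ², log-linked on a two-group design with
per-sample size-factor offsets:

    log μ_ij = b0_i + b1_i·[sample j treated] + log s_j

`size_factors` implements median-of-ratios (ratios to the per-feature
geometric mean over features with no zero counts), rescaled so the factors
have geometric mean 1; a total-count variant is provided for
accessibility-style counts. Dispersions α_i are method-of-moments on
normalized counts — pooled within-group, corrected for the mean 1/s_j, and
floored at 1e-8 / capped at 25 — with no shrinkage, trend, or outlier
filtering. The GLM is fit by iteratively reweighted least squares,
vectorized across features, with coefficients clamped at ±25 on the natural
log scale (an all-zero treated group therefore reports a large but finite
fold change rather than −∞).

The Wald statistic b1/se(b1) is referred to a **t distribution with n − 1
degrees of freedom** (n = samples in the contrast). This effective-df choice
was calibrated on null simulations at the design size that matters here
(2,000 null features, 3 vs 3, many seeds): the normal reference rejects at
~0.13 for a nominal 0.05 because moment dispersions are noisy and sometimes
collapse to the floor, while the nominal residual df (n − 2) is slightly
conservative (~0.039); n − 1 centres the type-I rate at ~0.05. Features
with baseMean below 1.0 get a missing adjusted p (treated downstream as not
significant); BH runs over the remaining features.

This module intentionally does **not** reproduce a full DESeq2 analysis: no
dispersion shrinkage, no Cook's filtering, no LFC moderation, and the
replicate covariate of a `~replicate + condition` design is omitted
(conditions are compared directly). The downstream science consumes only
the (baseMean, LFC, p, padj) interface, which is preserved.

FPKM is the textbook definition count / (length/1e3) / (libsize/1e6), with
library size defaulting to assigned-count column totals.

## Reversibility SOM

Selection: a gene enters clustering when padj < 0.05 and |LFC| > 1 in the
constant or either transient contrast, and is *excluded* when the same rule
fires in the control-vs-control contrast (guards against temperature /
RNAi-machinery confounds). Fold changes are clipped per column at the
empirical 5th/95th percentiles (numpy linear interpolation).

The multi-layer SOM uses a hexagonal grid (odd rows offset by ½, rows
√3/2 apart) with optional toroidal wrap-around (distances minimized over
the nine shifted copies of the plane). Genes: 3×2 toroidal grid, layer 1 =
constant LFC, layer 2 = the d9+d11 transient LFC pair. Peaks: 1×3 toroidal
grid with four single-column layers — the two clipped LFCs and the two
adjusted-p layers transformed to −log10(padj) capped at 20 (raw padj is
bounded and heavily skewed; the transform is this package's choice, made
once). Each layer is divided by its total variance before equal weighting,
so "similar weights" holds on comparable scales; the best matching unit
minimizes Σ_l w_l‖x_l − c_l‖² / Σ_l w_l with ties to the lowest unit index.

Training is the batch algorithm: 100 epochs, Gaussian neighbourhood with
radius decaying linearly from ⅔ of the maximal grid distance to 0, and
codebooks initialized from data rows. Three robustness measures matter on
grids this small, and all are deterministic given the seed:

* **Canonical-order init.** Rows are put in a lexicographic canonical order
  before the seeded sampling, so training is invariant to input row order.
* **Farthest-point init.** The first codebook is a seeded random row; the
  rest are greedy maximin picks in the weighted metric. Uniform sampling
  regularly starts two units inside one cluster, which batch training
  cannot always undo.
* **Diverse-schedule restarts + dead-unit rescue.** Training runs five
  times with progressively shorter neighbourhood phases (the last start is
  plain batch k-means from the farthest-point init); each run ends with a
  radius-zero refinement in which an empty unit is re-seeded on the
  worst-quantized row (never increases quantization error). The map with
  the lowest quantization error wins. Without this, roughly 40 % of seeds
  converged to a local optimum that merges the irreversible and reversible
  blobs onto one unit (QE 0.33 vs 0.12 for the correct map) — the cooling
  schedule, not the init, drives that optimum, so plain restarts do not
  escape it.

Unit labelling uses the codebook means with a "flat" band of δ = 0.5 log2
units: means above +δ in both layers → irreversible; constant only →
reversible; transient only → transient-specific; mirrored negatives form
the down clusters, which get ordinal names (down1…) by ascending
constant-layer mean. A unit matching no pattern is labelled by the nearest
idealized pattern with a warning, never silently. ATAC units: negative
constant mean → decreased; transient mean > δ → irreversible; otherwise
reversible.

## Interval rules

All coordinates are 0-based half-open. Consolidation keeps merged-replicate
calls with enrichment > 2 and q < 0.01 that overlap (≥ 1 bp) a passing call
(enrichment > 0, q < 0.05) in both replicates, then fuses survivors whose
separation is ≤ 250 bp (narrow marks) or ≤ 2.5 kb (broad marks). Domain
stitching fuses two consecutive domains exactly when the gap between them
is entirely covered by assembly-gap intervals. Polycomb-target
classification is boundary-inclusive (exactly 50 % body coverage counts).
The peak→TSS anchor is the interval midpoint (floor), distances are signed
(tss − midpoint), assignment minimizes |distance| with ties to the
lexicographically smaller gene id, peaks farther than 25 kb stay
unassigned, and |distance| > 1 kb marks a peak TSS-distal. The upstream
window for activating-mark hits is strand-aware (left of the body on "+",
right on "−") and clipped at zero. Every rule is tested against per-base /
all-pairs brute-force oracles on randomized genomes.

## Enrichment statistics

`fisher_greater` evaluates the exact hypergeometric upper tail
P(X ≥ a) (scipy's distribution function; tests verify it against direct
tail summation to 1e-12). Odds ratios are sample ORs with a Haldane 0.5
correction when a cell is zero. All Fisher tests in one call form a single
BH family. The Wilcoxon rank-sum test enumerates all C(n, n_x) rank splits
(mid-ranks, so ties are exact) up to combined n = 12 and uses the
tie-corrected normal approximation with continuity correction above;
two-sided p is 2·min(lower, upper tail) capped at 1.

## Motif model

Log2-odds scores use a 0.008 pseudocount (p' = (p + 0.008)/(1 + 4·0.008))
against the genome background (nucleotide frequencies of the supplied
windows/FASTA, not uniform). Scores are discretized once to 1e-3 log2
units; the threshold DP convolves the exact background distribution of the
integer score and returns the smallest *attained* score whose upper tail is
≤ the match p-value (5e-4 default), so DP, scanner, and the 4^L enumeration
oracle share one score space and agree exactly. Scanning covers both
strands; overlapping same-strand hits collapse greedily (left to right) to
the best-scoring position, and a start position matched on both strands
counts once. Windows containing non-ACGT characters never match at those
positions.

The regression stage standardizes counts (zero-variance columns drop out),
fits the L1 path over λ ∈ 10^(2, 1.9, …, −3) with 5-fold CV (fold split
seeded), takes coefficients at the CV-minimum λ, ranks motifs by
max(|coef_constant|, |coef_transient|) — zeros in both models never rank —
keeps the top 25, and refits the two OLS models whose t/p values are
reported; "selected" means p < 1e-5 in at least one model. Fewer than 50
peaks is rejected as unstable for CV.

## Variant summaries

Retention is strict where the rule says "greater": SNV/InDel kept iff
AF > 0.2, SV kept iff support ≥ 5 ("at least"), CNV kept iff copy ratio
> 1.5 or < 0.66. "Allelic fraction" for CNVs is interpreted as the copy
ratio the caller reports. Variant identity is (chrom, pos, ref, alt)
across samples; duplicate (sample, key) pairs deduplicate with a warning.
The AF spectrum reports the fraction strictly below the 0.2 cut (missing
for empty input); feature distributions are normalized within the
"control-found" and "shared by ≥ 2 tumours" groups, with unknown
categories bucketed as "other".

## Synthetic data: what it emulates, and what it does not

One root seed feeds `numpy.random.SeedSequence`, spawned into independent
named streams (counts, annotation, sequences, variants, regression), so
each component is reproducible on its own.

*Expression.* 2,000 genes by default (1,200 in the bundled cohort), six
perturbed classes at 6 % each (irreversible, reversible,
transient-specific, three mirrored down classes) plus an optional
control-confound class to exercise the exclusion path. Baselines are
log10-uniform in [1, 3]; per-gene dispersions are Gamma with mean 0.05
(shape 10); planted effects are ±2 log2 units applied in the
class-appropriate conditions; size factors are log-uniform in [0.5, 2].
Conditions: no knock-down, constant, transient day 9 and day 11, each with
a matched control-RNAi group, three replicates each.

*Accessibility.* 600–1,000 peaks with classes unaffected 60 % / reversible
20 % / irreversible 10 % / decreased 10 % and a planted effect of ±4.5
log2 units: accessibility gains at called differential peaks are strong,
and the t-referenced triplicate stand-in needs effects of that size to
reach the stringent padj < 1e-3 selection the analysis prescribes — a
deliberately chosen study condition, set once. Causal motif counts are
Poisson(0.5) per peak, raised to Poisson(2.0) in the motif's home class
(the activator's sites in irreversibly opened peaks, the repressor's in
decreased peaks), and each count adds ±0.5 log2 units to the peak's fold
change — so motif content carries the accessibility signal the regression
is supposed to find, as it does in tissue.

*Annotation.* Genes are placed non-overlapping with ≥ 1 kb spacing and
uniform strands; Polycomb-target genes (80 % of the irreversible and
reversible classes, 10 % background) are fully covered by planted
H3K27me3 domains, so every truth flag is recomputable by the ≥ 50 %
body-overlap rule. Planted confident peak calls pass all consolidation
thresholds; noise calls fail exactly one criterion drawn uniformly
(missing replicate, replicate q, merged enrichment, merged q). Window
sequences are drawn from an AT-rich background (0.29/0.21/0.21/0.29) with
the planted number of consensus occurrences inserted non-overlapping.

*Variants.* Twelve tumour and four control samples; private variant counts
are Poisson(60) per sample with Beta(1, 9) allele fractions (87 % of mass
below 0.2); 20 variant keys are planted in ≥ 2 tumour samples; small
numbers of SVs (support ~1 + Poisson(4)) and CNVs (log-normal ratios)
exercise the other retention branches; features follow a fixed
exon/intron/UTR/intergenic/other mix (0.15/0.45/0.08/0.30/0.02).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level artefacts (mapping bias, GC
effects, duplicates), asymmetric up/down regulation (the real response is
dominated by down-regulation; the planted classes are symmetric),
mean-dependent dispersion trends, correlated genes or peaks (everything is
independent given the class), chromatin-state autocorrelation along the
genome, background motif co-occurrence structure, and sub-clonal tumour
architecture. Conclusions about statistical power on real data should not
be read off these simulations; the tests establish correctness of the
rules and estimators, and recoverability under the planted conditions.

## Problem sizes and determinism

The bundled analyses run on 1,200 genes / 600 peaks / 16 variant samples;
the acceptance script uses 2,000-feature null and recovery simulations, 20
clustering seeds, 100 randomized oracle genomes and 20 regression
replicates — sizes chosen so the complete test suite and the acceptance
script each finish in about a minute on one CPU while keeping Monte-Carlo
error well inside the asserted margins. All floating-point table output is
rounded to 6 decimals before writing, making report files byte-identical
across runs and platforms under a fixed seed.
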