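# epireversion

Analysis pipeline for classifying gene-expression and chromatin changes as
**reversible** or **irreversible** after a *transient* epigenetic
perturbation — the situation in which a Polycomb (PRC1) subunit is depleted
for a short pulse during development, restored, and the tissue nevertheless
keeps a stable tumour-like transcriptional state. The package implements the
downstream statistical analysis of such an experiment and ships a
synthetic-data generator with planted ground truth, so the entire pipeline
runs and is tested without any sequencing data.

It is written for computational biologists who want to reproduce or adapt
this style of multi-omic analysis: RNA-seq count matrices across knock-down
conditions, CUT&RUN/ChIP/ATAC peak calls, PWM motif collections and somatic
variant tables all come in as plain-text files.

## What it computes

**Differential testing.** A two-group negative-binomial Wald test
(`epireversion.differential`) produces the usual quadruple per feature —
baseMean, log2 fold change, p, BH-adjusted p — with median-of-ratios or
total-count size factors. It is a documented simplified stand-in for a full
DESeq2 analysis: method-of-moments dispersions, no shrinkage, and a
t-referenced Wald statistic calibrated for triplicate designs
(see `docs/methods.md`).

**Reversibility clustering.** Genes significant after constant *or*
transient knock-down (padj < 0.05, |LFC| > 1), but clean in the
control-vs-control contrast, are clipped at the 5th/95th percentiles and
clustered with a two-layer self-organizing map on a 3×2 toroidal hexagonal
grid (layer 1: constant-KD LFC; layer 2: the two transient timepoints).
Units are labelled from their codebook sign patterns:

| codebook means            | label               |
|---------------------------|---------------------|
| constant ↑, transient ↑   | irreversible        |
| constant ↑, transient ≈ 0 | reversible          |
| constant ≈ 0, transient ↑ | transient-specific  |
| mirrored negatives        | down1 / down2 / down3 |

ATAC peaks pass a stricter filter (padj < 1e-3, |LFC| > 1, log10 baseMean
≥ 1.25) and a four-layer SOM on a 1×3 grid splits them into irreversible /
reversible / decreased accessibility classes.

**Interval rules.** Confident-peak consolidation (detected in both
replicates at enrichment > 0 & q < 0.05 *and* in merged replicates at
enrichment > 2 & q < 0.01, then fused with a 250 bp / 2.5 kb gap), gap-aware
domain stitching, Polycomb-target classification (≥ 50 % of the gene body
inside an H3K27me3 domain), activating-mark gene hits (gene body or 2.5 kb
upstream of the TSS), and nearest-TSS peak assignment within 25 kb with a
1 kb TSS-distal flag.

**Enrichment statistics.** One-sided Fisher tests (exact hypergeometric
upper tail) of gene sets against clusters, BH FDR, and the two-sided
Wilcoxon rank-sum test (exact enumeration up to combined n = 12).

**Motif model.** PWM occurrences are counted in peak-centre ± 250 bp windows
at an exact match p-value threshold (5e-4, genome background) computed by
dynamic programming; two LASSO regressions over the fixed lambda grid
10^(2 … −3) with seeded 5-fold CV predict constant/transient accessibility
fold changes from motif counts; the top-25 |coefficient| motifs are refit by
OLS and motifs with p < 1e-5 in at least one model are reported, plus
motif-count dose-response summaries.

**Variant summaries.** Retention filtering (SNV/InDel allele fraction > 0.2,
SV ≥ 5 supporting reads, CNV ratio > 1.5 or < 0.66), allele-frequency
spectra, cross-sample sharing of variant keys, and feature-category
distributions — the analysis used to argue that no recurrent driver
mutation underlies the tumours.

## Worked example

The numbered scripts under `analysis/` run the whole study on one seeded
synthetic cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_differential_expression.py
python analysis/03_gene_reversibility_clusters.py
python analysis/04_atac_clusters.py
python analysis/05_motif_model.py
python analysis/06_somatic_variants.py
```

Script 03 prints, for the bundled seed-42 cohort of 1,200 genes:

```
cluster sizes:
cluster
unaffected            791
irreversible           72
transient-specific     71
reversible             68
down3                  67
down1                  67
down2                  64

Polycomb-target over-representation (one-sided Fisher, BH FDR):
           cluster  a  odds_ratio          fdr tier
      irreversible 57   20.280899 6.673155e-29 ****
        reversible 54   20.265983 1.048012e-27 ****
transient-specific 33    3.985279 2.329056e-07 ****
```

i.e. the map recovers the planted 72-gene classes almost exactly, and the
up-regulated clusters are strongly enriched for Polycomb-target genes
(odds ratios ≈ 20), as expected when de-repression of Polycomb domains
drives the response. Script 05 reports the two planted causal motifs — and
only those — as significant predictors of accessibility change:

```
motifs with p < 1e-5 in at least one linear model:
  motif  coef_constant  coef_transient  t_constant  t_transient
Stat92E          0.630           0.942       4.741        7.215
   zfh1         -1.307          -1.164      -8.646       -8.527
```

with monotone dose-response medians (more Stat92E motifs → larger
accessibility gain; more zfh1 motifs → larger loss). Script 06 prints the
variant argument: 87 % of simulated allele fractions below 0.2, and 98 % of
retained variants private to a single tumour sample.

The same stages are available as a CLI (`epireversion simulate | diffexp |
peaks … | classify-peaks | enrich | motif-model | variants | run`); 
`epireversion run --config analysis/pipeline_config.yaml` executes
everything from one YAML, deterministic under its seed.

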