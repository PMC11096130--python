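#!/usr/bin/env python
"""Cluster differential accessibility peaks and link them to genes.

Peaks passing the stringent accessibility filter (padj < 1e-3, |LFC| > 1,
log10 baseMean >= 1.25) are clustered with a four-layer SOM on a 1x3 grid
(clipped constant/transient LFCs plus the two -log10 padj layers) into
irreversible / reversible / decreased classes.  Consolidation of the
planted replicate peak calls is checked against truth, and peak classes
are cross-tabulated against the RNA clusters by nearest-TSS assignment.
"""

from pathlib import Path

import pandas as pd

from epireversion import io as eio
from epireversion.differential import Contrast, nb_wald_test
from epireversion.intervals import consolidate_peaks
from epireversion.simulate import SyntheticTruth
from epireversion.som import select_and_cluster_atac

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"
SEED = 42

counts = eio.read_counts(COHORT / "peak_counts.tsv")
design = eio.read_design(COHORT / "design.tsv")
counts = eio.align_design(counts, design)

atac = {}
for cond in ("constant", "transient_d11"):
    atac[cond] = nb_wald_test(counts, design, Contrast(f"{cond}_ph", f"{cond}_w"))
    atac[cond].round(6).to_csv(ROOT / f"atac_de_{cond}.tsv", sep="\t", index=False)

classes, model = select_and_cluster_atac(atac["constant"], atac["transient_d11"],
                                         seed=SEED)
classes.round(6).to_csv(ROOT / "peak_classification.tsv", sep="\t", index=False)
print("accessibility clusters:")
print(classes["cluster"].value_counts().to_string())

truth = SyntheticTruth.from_json(COHORT / "truth.json")
canon = {"increased_irreversible": "irreversible",
         "increased_reversible": "reversible", "decreased": "decreased"}
true = pd.Series(truth.peak_class).map(canon)
joined = classes.set_index("peak").join(true.rename("true")).dropna()
acc = float((joined["cluster"] == joined["true"]).mean())
print(f"\nagreement with planted classes among selected peaks: {acc:.3f}")

rep1 = eio.read_narrowpeak(COHORT / "peakcalls_rep1.tsv")
rep2 = eio.read_narrowpeak(COHORT / "peakcalls_rep2.tsv")
merged = eio.read_narrowpeak(COHORT / "peakcalls_merged.tsv")
conf = consolidate_peaks(rep1, rep2, merged, mode="narrow")
print(f"consolidation: {len(conf)} confident peaks "
      f"(planted: {len(truth.confident_peaks)} confident, "
      f"{len(truth.noise_peaks)} noise)")
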