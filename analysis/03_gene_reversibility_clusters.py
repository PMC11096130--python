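#!/usr/bin/env python
"""Cluster differential genes into reversibility classes and test Polycomb
binding per cluster.

Genes significant after constant or transient knock-down (and clean in the
control contrast) are clipped at the 5th/95th percentiles and clustered
with a two-layer SOM on a 3x2 toroidal hexagonal grid (layer 1: constant
LFC; layer 2: the two transient timepoints).  Units are labelled from
their codebook sign patterns; Polycomb-target over-representation per
cluster is then assessed with one-sided Fisher tests (the up-clusters,
and the irreversible cluster in particular, should be enriched).
"""

from pathlib import Path

import pandas as pd

from epireversion import io as eio
from epireversion.enrichment import overrepresentation_by_cluster
from epireversion.intervals import classify_pcg_targets, merge_intervals
from epireversion.som import (HexGrid, clip_percentiles, label_gene_clusters,
                              select_de_genes, train_supersom)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 42

results = {c: pd.read_csv(ROOT / f"de_{c}.tsv", sep="\t")
           for c in ("no_kd", "constant", "transient_d9", "transient_d11")}
lfc = select_de_genes({c: results[c] for c in
                       ("constant", "transient_d9", "transient_d11")},
                      results["no_kd"])
clipped = clip_percentiles(lfc)
model = train_supersom(
    [clipped[["constant"]].to_numpy(),
     clipped[["transient_d9", "transient_d11"]].to_numpy()],
    HexGrid(3, 2, toroidal=True), seed=SEED)
classes = label_gene_clusters(model, clipped).set_index("feature_id")

genes = eio.read_gene_annotation(ROOT / "cohort" / "genes.tsv")
domains = eio.read_bed(ROOT / "cohort" / "h3k27me3_domains.bed")
pcg = classify_pcg_targets(genes, merge_intervals(domains)).set_index("gene_id")

table = pd.DataFrame(index=pd.Index(results["constant"]["feature_id"], name="feature_id"))
table["cluster"] = classes["cluster"].reindex(table.index).fillna("unaffected")
table["PcG_bound"] = pcg["pcg_target"].reindex(table.index).fillna(False)
table.round(6).to_csv(ROOT / "gene_classification.tsv", sep="\t")
print("cluster sizes:")
print(table["cluster"].value_counts().to_string())

universe = results["constant"].loc[results["constant"]["padj"].notna(), "feature_id"]
in_univ = table.index.isin(set(universe))
enr = overrepresentation_by_cluster(
    table.loc[in_univ, "cluster"],
    {"PcG_target": set(table.index[table["PcG_bound"] & in_univ])},
    list(universe))
enr.round(6).to_csv(ROOT / "pcg_enrichment.tsv", sep="\t", index=False)
print("\nPolycomb-target over-representation (one-sided Fisher, BH FDR):")
print(enr[["cluster", "a", "odds_ratio", "fdr", "tier"]].to_string(index=False))
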