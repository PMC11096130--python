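"""Post-calling somatic-variant summaries.

Retention filtering of typed variant records, the allele-frequency
spectrum, cross-sample sharing of variant keys, and feature-category
distributions of selected variant groups.  Variant calling itself happens
upstream; records arrive as a flat per-sample table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "retention_filter",
    "af_spectrum",
    "sharing_spectrum",
    "feature_distribution",
]

AF_RETAIN = 0.2          # SNV/InDel kept iff AF strictly greater
SV_MIN_SUPPORT = 5       # SV kept iff supported by at least this many reads
CNV_DUP_RATIO = 1.5      # CNV kept iff ratio strictly greater (duplication) ...
CNV_DEL_RATIO = 0.66     # ... or strictly smaller (deletion)
FEATURE_CATEGORIES = ["exon", "intron", "UTR", "intergenic", "other"]
KEY_COLS = ["chrom", "pos", "ref", "alt"]


def retention_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep variants passing the type-specific evidence thresholds.

    SNV/InDel: allele fraction > 0.2 (strict).  SV: >= 5 supporting reads.
    CNV: copy ratio > 1.5 or < 0.66 (both strict).  A record missing the
    evidence field its type requires is an error.
    """
    snv = variants["vtype"].isin(["SNV", "InDel"])
    sv = variants["vtype"] == "SV"
    cnv = variants["vtype"] == "CNV"
    unknown = ~(snv | sv | cnv)
    if unknown.any():
        raise ValueError(f"unknown vtype {variants.loc[unknown, 'vtype'].iloc[0]!r}")
    if variants.loc[snv, "allele_fraction"].isna().any():
        raise ValueError("SNV/InDel record missing allele_fraction")
    if variants.loc[sv, "support_reads"].isna().any():
        raise ValueError("SV record missing support_reads")
    if variants.loc[cnv, "copy_ratio"].isna().any():
        raise ValueError("CNV record missing copy_ratio")
    keep = np.zeros(len(variants), dtype=bool)
    keep[snv.to_numpy()] = (variants.loc[snv, "allele_fraction"] > AF_RETAIN).to_numpy()
    keep[sv.to_numpy()] = (variants.loc[sv, "support_reads"] >= SV_MIN_SUPPORT).to_numpy()
    ratio = variants.loc[cnv, "copy_ratio"]
    keep[cnv.to_numpy()] = ((ratio > CNV_DUP_RATIO) | (ratio < CNV_DEL_RATIO)).to_numpy()
    return variants[keep].reset_index(drop=True)


def af_spectrum(variants: pd.DataFrame, cut: float = AF_RETAIN,
                bin_width: float = 0.05) -> dict:
    """Allele-frequency histogram of SNV/InDel records plus fraction below cut.

    Returns ``{"histogram": DataFrame(bin_left, bin_right, count),
    "fraction_below_cut": float or nan, "n": int}``; the fraction uses a
    strict ``af < cut`` comparison and is NaN for empty input.
    """
    af = variants.loc[variants["vtype"].isin(["SNV", "InDel"]), "allele_fraction"]
    af = af.dropna().to_numpy()
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(af, bins=edges)
    frame = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist})
    frac = float((af < cut).mean()) if af.size else float("nan")
    return {"histogram": frame, "fraction_below_cut": frac, "n": int(af.size)}


def sharing_spectrum(variants: pd.DataFrame, tumour_samples) -> dict:
    """How many tumour samples carry each variant key.

    Variant identity is (chrom, pos, ref, alt) across samples; duplicate
    (sample, key) pairs are deduplicated with a warning.  Returns the
    per-key carrier counts, a histogram over counts, and the fraction of
    keys private to a single tumour sample.
    """
    tumour_samples = list(tumour_samples)
    sub = variants[variants["sample_id"].isin(tumour_samples)]
    dedup = sub.drop_duplicates(subset=["sample_id"] + KEY_COLS)
    if len(dedup) < len(sub):
        warnings.warn(f"{len(sub) - len(dedup)} duplicate (sample, variant) pairs removed")
    carriers = (dedup.groupby(KEY_COLS, sort=True)["sample_id"]
                .nunique().rename("n_tumour_samples").reset_index())
    hist = (carriers["n_tumour_samples"].value_counts().sort_index()
            .rename_axis("n_samples").rename("n_variants").reset_index())
    frac_private = (float((carriers["n_tumour_samples"] == 1).mean())
                    if len(carriers) else float("nan"))
    return {"carriers": carriers, "histogram": hist, "fraction_private": frac_private}


def feature_distribution(variants: pd.DataFrame, control_samples,
                         tumour_samples) -> pd.DataFrame:
    """Feature-category proportions of two variant groups.

    Group "control-found": variant keys seen in any control sample.  Group
    "shared>=2-tumours": keys carried by at least two tumour samples.
    Unknown categories are bucketed as "other" with a warning; proportions
    are NaN for an empty group.
    """
    v = variants.copy()
    bad = ~v["feature"].isin(FEATURE_CATEGORIES)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} records with unknown feature category -> 'other'")
        v.loc[bad, "feature"] = "other"

    control_keys = v[v["sample_id"].isin(list(control_samples))]
    shared = sharing_spectrum(v, tumour_samples)["carriers"]
    shared_keys = shared[shared["n_tumour_samples"] >= 2][KEY_COLS]
    tumour_shared = v.merge(shared_keys, on=KEY_COLS).drop_duplicates(subset=KEY_COLS)
    control_found = control_keys.drop_duplicates(subset=KEY_COLS)

    rows = {}
    for name, group in (("control-found", control_found), ("shared>=2-tumours", tumour_shared)):
        if len(group) == 0:
            rows[name] = {cat: float("nan") for cat in FEATURE_CATEGORIES}
        else:
            props = group["feature"].value_counts(normalize=True)
            rows[name] = {cat: float(props.get(cat, 0.0)) for cat in FEATURE_CATEGORIES}
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out[FEATURE_CATEGORIES]
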