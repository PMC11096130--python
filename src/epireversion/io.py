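"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are held internally as 0-based, half-open
``[start, end)`` intervals.  BED and narrowPeak-like files already use that
convention; the minimal VCF reader converts its 1-based ``POS`` at the
boundary (variant tables keep 1-based ``pos`` because that is how variants
are reported everywhere downstream).

Readers validate strictly and raise :class:`FormatError` carrying the file
name and line number rather than coercing malformed records.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "align_design",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_variants",
    "write_variants",
    "read_vcf_minimal",
    "read_pwms",
    "write_pwms",
    "read_fasta",
    "write_fasta",
    "load_yaml",
]

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "vtype",
    "allele_fraction", "support_reads", "copy_ratio", "feature", "deleterious",
]


class FormatError(ValueError):
    """Malformed input; message carries file and line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _open_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into columns chrom/start/end/name/strand.

    Strand defaults to "." when the file has fewer than 6 columns.
    """
    rows = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(path, lineno, "BED record needs at least 3 columns")
        chrom = fields[0]
        if not chrom:
            raise FormatError(path, lineno, "empty chrom")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(path, lineno, f"non-integer coordinates: {fields[1]!r}, {fields[2]!r}")
        if start < 0:
            raise FormatError(path, lineno, f"negative start {start}")
        if start >= end:
            raise FormatError(path, lineno, f"start {start} >= end {end} (0-based half-open)")
        name = fields[3] if len(fields) > 3 else "."
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in {"+", "-", "."}:
            raise FormatError(path, lineno, f"bad strand {strand!r}")
        rows.append((chrom, start, end, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out:
        out["name"] = "."
    if "strand" not in out:
        out["strand"] = "."
    out["score"] = 0
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# narrowPeak-like peak tables

def read_narrowpeak(path, qvalue_scale: str = "linear") -> pd.DataFrame:
    """Read a headered narrowPeak-like TSV with peak-call statistics.

    Required columns: chrom, start, end, name, enrichment and either
    ``qvalue`` (``qvalue_scale="linear"``) or ``neglog10_qvalue``
    (``qvalue_scale="neglog10"``).  The scale is chosen explicitly by the
    caller, never guessed from the values.  q-values are returned on the
    linear scale in [0, 1].
    """
    if qvalue_scale not in {"linear", "neglog10"}:
        raise ValueError(f"unknown qvalue_scale {qvalue_scale!r}")
    df = pd.read_csv(path, sep="\t")
    qcol = "qvalue" if qvalue_scale == "linear" else "neglog10_qvalue"
    for col in ["chrom", "start", "end", "name", "enrichment", qcol]:
        if col not in df.columns:
            raise FormatError(path, 1, f"missing required column {col!r}")
    if (df["enrichment"] < 0).any():
        lineno = int(df.index[df["enrichment"] < 0][0]) + 2
        raise FormatError(path, lineno, "negative enrichment")
    if (df["start"] >= df["end"]).any():
        lineno = int(df.index[df["start"] >= df["end"]][0]) + 2
        raise FormatError(path, lineno, "start >= end")
    if qvalue_scale == "neglog10":
        if (df[qcol] < 0).any():
            lineno = int(df.index[df[qcol] < 0][0]) + 2
            raise FormatError(path, lineno, "negative -log10(q)")
        df["qvalue"] = 10.0 ** (-df[qcol])
        df = df.drop(columns=[qcol])
    else:
        bad = (df["qvalue"] < 0) | (df["qvalue"] > 1)
        if bad.any():
            lineno = int(df.index[bad][0]) + 2
            raise FormatError(path, lineno, "qvalue outside [0, 1]")
    if "replicate" not in df.columns:
        df["replicate"] = "merged"
    cols = ["chrom", "start", "end", "name", "enrichment", "qvalue", "replicate"]
    return df[cols].sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "name", "enrichment", "qvalue"]
    if "replicate" in df.columns:
        cols = cols + ["replicate"]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts and design

def read_counts(path) -> pd.DataFrame:
    """Read a features x samples TSV of integer counts (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for j, col in enumerate(df.columns):
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            i = int(np.argmax(numeric.isna().to_numpy()))
            raise FormatError(path, i + 2, f"non-numeric cell at feature {df.index[i]!r}, sample {col!r}")
        if not np.allclose(numeric, np.round(numeric)):
            i = int(np.argmax(~np.isclose(numeric, np.round(numeric))))
            raise FormatError(path, i + 2, f"non-integer count at feature {df.index[i]!r}, sample {col!r}")
        if (numeric < 0).any():
            i = int(np.argmax((numeric < 0).to_numpy()))
            raise FormatError(path, i + 2, f"negative count at feature {df.index[i]!r}, sample {col!r}")
    out = df.astype(np.int64)
    out.index.name = "feature_id"
    return out


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "condition", "rnai_target", "replicate", "matched_control"]
    for col in required:
        if col not in df.columns:
            raise FormatError(path, 1, f"missing design column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(path, 1, f"duplicated sample_id {dup!r}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def align_design(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Check that every design sample has a counts column; return counts ordered as the design."""
    missing = [s for s in design["sample_id"] if s not in counts.columns]
    if missing:
        raise ValueError(f"design samples absent from count matrix: {missing}")
    return counts[list(design["sample_id"])]


# ---------------------------------------------------------------------------
# gene models

def read_gene_annotation(path) -> pd.DataFrame:
    """Gene models TSV: gene_id, chrom, start, end, strand, tss.

    Gene bodies are 0-based half-open.  The TSS is the strand-aware 5' end:
    ``start`` on "+", ``end - 1`` on "-"; mismatches are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand", "tss"]
    for col in required:
        if col not in df.columns:
            raise FormatError(path, 1, f"missing gene column {col!r}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(path, int(df.index[bad][0]) + 2, "gene strand must be + or -")
    if (df["start"] >= df["end"]).any():
        raise FormatError(path, int(df.index[df["start"] >= df["end"]][0]) + 2, "zero-length gene body")
    expected = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    if (df["tss"] != expected).any():
        i = int(np.argmax((df["tss"] != expected).to_numpy()))
        raise FormatError(path, i + 2, f"tss inconsistent with strand for {df['gene_id'].iloc[i]!r}")
    return df.reset_index(drop=True)


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand", "tss"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants

def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ["sample_id", "chrom", "pos", "ref", "alt", "vtype", "feature"]:
        if col not in df.columns:
            raise FormatError(path, 1, f"missing variant column {col!r}")
    bad = ~df["vtype"].isin(["SNV", "InDel", "SV", "CNV"])
    if bad.any():
        raise FormatError(path, int(df.index[bad][0]) + 2,
                          f"unknown vtype {df['vtype'][bad].iloc[0]!r}")
    for col in ["allele_fraction", "support_reads", "copy_ratio"]:
        if col not in df.columns:
            df[col] = np.nan
    if "deleterious" not in df.columns:
        df["deleterious"] = False
    af = df["allele_fraction"]
    snv = df["vtype"].isin(["SNV", "InDel"])
    bad_af = snv & (af.isna() | (af <= 0) | (af > 1))
    if bad_af.any():
        raise FormatError(path, int(df.index[bad_af][0]) + 2,
                          "SNV/InDel allele_fraction must be in (0, 1]")
    return df[VARIANT_COLUMNS].reset_index(drop=True)


def write_variants(variants: pd.DataFrame, path) -> None:
    variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_vcf_minimal(path, sample_id: str) -> pd.DataFrame:
    """Read a minimal single-sample VCF into the native variant-table layout.

    Only CHROM, POS, REF, ALT and the allele fraction are consumed; AF is
    taken from the INFO ``AF=`` key, or computed from FORMAT ``AD`` of the
    first genotype column when INFO lacks it.  Records are typed SNV/InDel
    from REF/ALT lengths; multi-allelic records are split.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(path, lineno, "VCF record needs at least 8 columns")
            chrom, pos, _, ref, alts, _, _, info = fields[:8]
            try:
                pos = int(pos)
            except ValueError:
                raise FormatError(path, lineno, f"non-integer POS {pos!r}")
            info_d = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            afs = None
            if "AF" in info_d:
                afs = [float(x) for x in info_d["AF"].split(",")]
            elif len(fields) >= 10:
                fmt = fields[8].split(":")
                sample = fields[9].split(":")
                if "AD" in fmt:
                    ad = [int(x) for x in sample[fmt.index("AD")].split(",")]
                    total = sum(ad)
                    if total > 0:
                        afs = [a / total for a in ad[1:]]
            alt_list = alts.split(",")
            if afs is None:
                raise FormatError(path, lineno, "no AF in INFO and no AD in FORMAT")
            if len(afs) != len(alt_list):
                raise FormatError(path, lineno, "AF count does not match ALT count")
            for alt, af in zip(alt_list, afs):
                vtype = "SNV" if len(ref) == 1 and len(alt) == 1 else "InDel"
                rows.append((sample_id, chrom, pos, ref, alt, vtype, af,
                             np.nan, np.nan, "other", False))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# PWMs (JASPAR-like text) and FASTA

def read_pwms(path):
    """Read JASPAR-like PWM text into a list of (motif_id, matrix) pairs.

    Format::

        >motif_id
        A [ 3  0 12 ]
        C [ 0  1  0 ]
        G [ 9 11  0 ]
        T [ 0  0  0 ]

    Rows may be counts or probabilities; columns are normalized to sum to 1.
    """
    motifs = []
    current_id, rows = None, {}

    def _finish(lineno):
        if current_id is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(path, lineno, f"motif {current_id!r} missing base rows")
        mat = np.array([rows[b] for b in "ACGT"], dtype=float).T  # positions x 4
        colsums = mat.sum(axis=1)
        if (colsums <= 0).any():
            raise FormatError(path, lineno, f"motif {current_id!r} has an empty column")
        motifs.append((current_id, mat / colsums[:, None]))

    lineno = 0
    for lineno, line in _open_lines(path):
        if line.startswith(">"):
            _finish(lineno)
            current_id = line[1:].split()[0]
            rows = {}
        else:
            parts = line.replace("[", " ").replace("]", " ").split()
            if not parts or parts[0] not in "ACGT":
                raise FormatError(path, lineno, f"unparseable PWM row {line!r}")
            rows[parts[0]] = [float(x) for x in parts[1:]]
    _finish(lineno + 1)
    return motifs


def write_pwms(motifs, path) -> None:
    with open(path, "w") as fh:
        for motif_id, mat in motifs:
            fh.write(f">{motif_id}\n")
            for j, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in np.asarray(mat)[:, j])
                fh.write(f"{base} [ {vals} ]\n")


def read_fasta(path) -> dict:
    seqs, name, chunks = {}, None, []
    for _, line in _open_lines(path):
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip().upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
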