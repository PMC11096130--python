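"""Synthetic multi-omic inputs with planted ground truth.

Emulates the statistical structure of a transient-perturbation study in a
developing tissue: negative-binomial RNA counts across a no-knock-down
control, a constant knock-down, and a transient knock-down sampled at two
recovery timepoints (each with temperature-matched RNAi controls); planted
gene classes (reversible / irreversible / transient-specific and three
mirrored down classes); repressive-mark domains over planted Polycomb
target genes; accessibility peaks whose fold changes combine a planted
peak class with a linear function of planted motif counts; per-replicate
peak calls engineered to pass or fail the consolidation rule; and
per-sample somatic variant tables dominated by private low-allele-fraction
variants.

Every planted flag is recomputable from the emitted files by the
downstream modules' rules, so the whole pipeline is testable with no
external data.  All randomness flows from one root seed through
``numpy.random.SeedSequence`` spawning, one child stream per component
(counts, annotation, sequences, variants), so components are reproducible
independently of each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "simulate_counts",
    "simulate_annotation",
    "simulate_variants",
    "simulate_motif_regression",
    "simulate_cohort",
]

GENE_CLASSES = ["unaffected", "irreversible", "reversible", "transient_specific",
                "down1", "down2", "down3", "control_confound"]
PEAK_CLASSES = ["unaffected", "increased_irreversible", "increased_reversible", "decreased"]

# Planted LFC multiplier per (gene class, condition); down classes mirror the
# up classes: down1 both, down2 constant-only, down3 transient-only.
CLASS_PATTERNS = {
    "unaffected":         {"no_kd": 0, "constant": 0, "transient_d9": 0, "transient_d11": 0},
    "irreversible":       {"no_kd": 0, "constant": 1, "transient_d9": 1, "transient_d11": 1},
    "reversible":         {"no_kd": 0, "constant": 1, "transient_d9": 0, "transient_d11": 0},
    "transient_specific": {"no_kd": 0, "constant": 0, "transient_d9": 1, "transient_d11": 1},
    "down1":              {"no_kd": 0, "constant": -1, "transient_d9": -1, "transient_d11": -1},
    "down2":              {"no_kd": 0, "constant": -1, "transient_d9": 0, "transient_d11": 0},
    "down3":              {"no_kd": 0, "constant": 0, "transient_d9": -1, "transient_d11": -1},
    "control_confound":   {"no_kd": 1, "constant": 1, "transient_d9": 1, "transient_d11": 1},
}
PEAK_PATTERNS = {
    "unaffected":             {"constant": 0, "transient_d11": 0},
    "increased_irreversible": {"constant": 1, "transient_d11": 1},
    "increased_reversible":   {"constant": 1, "transient_d11": 0},
    "decreased":              {"constant": -1, "transient_d11": -1},
}

# High-information consensus motifs for the two planted causal factors plus a
# namespace for decoys (synthetic stand-ins, not database matrices).
CAUSAL_CONSENSUS = {"Stat92E": "TTCCCGGAA", "zfh1": "CACCTG"}

# Peak class whose members carry extra copies of each causal motif: the
# activator's sites drive irreversible opening, the repressor's sites mark
# the peaks that lose accessibility.
MOTIF_HOME_CLASS = {"Stat92E": "increased_irreversible", "zfh1": "decreased"}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 2000
    n_peaks: int = 1000
    chrom_lengths: dict = field(default_factory=lambda: {
        "2L": 8_000_000, "2R": 8_000_000, "3L": 8_000_000,
        "3R": 8_000_000, "X": 8_000_000,
    })
    class_fractions: dict = field(default_factory=lambda: {
        "unaffected": 0.64, "irreversible": 0.06, "reversible": 0.06,
        "transient_specific": 0.06, "down1": 0.06, "down2": 0.06, "down3": 0.06,
        "control_confound": 0.0,
    })
    peak_class_fractions: dict = field(default_factory=lambda: {
        "unaffected": 0.60, "increased_irreversible": 0.10,
        "increased_reversible": 0.20, "decreased": 0.10,
    })
    n_replicates: int = 3
    conditions: tuple = ("no_kd", "constant", "transient_d9", "transient_d11")
    base_mean_log_range: tuple = (1.0, 3.0)        # log10 of baseline mean counts
    peak_base_mean_log_range: tuple = (0.8, 3.0)   # some peaks fail the 1.25 floor
    dispersion: float = 0.05                        # mean NB dispersion
    dispersion_shape: float = 10.0                  # gamma shape of per-gene dispersion
    effect_size_lfc: float = 2.0                    # planted |log2 FC| for perturbed gene classes
    peak_effect_size_lfc: float = 4.5               # planted |log2 FC| for perturbed peak classes
    motif_betas: dict = field(default_factory=lambda: {"Stat92E": 0.5, "zfh1": -0.5})
    motif_count_rate: float = 0.5                   # Poisson occurrences per peak
    motif_class_rate: float = 2.0                   # rate inside the motif's home class
    n_decoy_motifs: int = 18
    window_flank: int = 250
    pcg_target_rate: dict = field(default_factory=lambda: {
        "irreversible": 0.8, "reversible": 0.8, "transient_specific": 0.4,
        "down1": 0.1, "down2": 0.1, "down3": 0.1, "unaffected": 0.1,
        "control_confound": 0.1,
    })
    n_confident_peaks: int = 100
    n_noise_peaks: int = 100
    n_tumour_samples: int = 12
    n_control_samples: int = 4
    variant_private_rate: float = 60.0
    variant_shared_count: int = 20
    af_beta_params: tuple = (1.0, 9.0)

    def validate(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if abs(sum(self.peak_class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("peak_class_fractions must sum to 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class labels {sorted(unknown)}")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if min(self.n_genes, self.n_peaks, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        a, b = self.af_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("af_beta_params must be positive")
        if "no_kd" not in self.conditions or len(self.conditions) < 2:
            raise ValueError("conditions must include the control and a perturbed condition")

    def streams(self) -> dict:
        """Named child RNGs spawned from the root seed."""
        root = np.random.SeedSequence(self.seed)
        names = ["counts", "annotation", "sequences", "variants", "regression"]
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticTruth:
    gene_class: dict = field(default_factory=dict)        # gene_id -> class
    pcg_target: dict = field(default_factory=dict)        # gene_id -> bool
    peak_class: dict = field(default_factory=dict)        # peak -> class
    peak_motif_counts: dict = field(default_factory=dict)  # peak -> {motif: count}
    peak_effect: dict = field(default_factory=dict)       # peak -> {condition: lfc}
    confident_peaks: list = field(default_factory=list)   # names that must survive consolidation
    noise_peaks: list = field(default_factory=list)
    variant_carriers: dict = field(default_factory=dict)  # "chrom:pos:ref:alt" -> [samples]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _draw_classes(rng, n, fractions: dict, labels) -> np.ndarray:
    """Deterministic class counts from fractions (largest remainder), shuffled."""
    labels = [c for c in labels if fractions.get(c, 0) > 0]
    fracs = np.array([fractions[c] for c in labels])
    base = np.floor(fracs * n).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(fracs * n - base))
    for i in range(rem):
        base[order[i % len(labels)]] += 1
    out = np.repeat(labels, base)
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# counts

def _design_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for target, role in (("ph", "kd"), ("w", "ctl")):
            for r in range(1, config.n_replicates + 1):
                rows.append({
                    "sample_id": f"{cond}_{target}_r{r}",
                    "condition": f"{cond}_{target}",
                    "rnai_target": target,
                    "replicate": f"r{r}",
                    "matched_control": f"{cond}_w",
                })
    return pd.DataFrame(rows)


def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with Var = mu + alpha mu^2 via numpy's (n, p) parameterization."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(config: SimulationConfig, truth: SyntheticTruth | None = None):
    """Gene and peak count matrices plus the sample design sheet.

    Counts are NB draws with mean = baseline x 2^(planted LFC) x sample size
    factor; size factors are log-uniform in [0.5, 2].  Planted LFCs follow
    the class patterns (knock-down samples only; matched RNAi controls stay
    at baseline).  Peak means additionally include the linear motif-count
    effect shared with the regression stage.
    """
    config.validate()
    rng = config.streams()["counts"]
    truth = truth if truth is not None else SyntheticTruth()
    design = _design_frame(config)
    n_samp = len(design)
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samp))

    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    classes = _draw_classes(rng, config.n_genes, config.class_fractions, GENE_CLASSES)
    truth.gene_class = dict(zip(gene_ids, (str(c) for c in classes)))
    lo, hi = config.base_mean_log_range
    base = 10.0 ** rng.uniform(lo, hi, size=config.n_genes)
    alpha = rng.gamma(config.dispersion_shape,
                      config.dispersion / config.dispersion_shape, size=config.n_genes)
    alpha = np.clip(alpha, 1e-6, None)

    cond_label = design["condition"].str.rsplit("_", n=1).str[0].to_numpy()
    is_kd = (design["rnai_target"] == "ph").to_numpy()
    lfc = np.zeros((config.n_genes, n_samp))
    for j in range(n_samp):
        if not is_kd[j]:
            continue
        cond = cond_label[j]
        pat = np.array([CLASS_PATTERNS[c][cond] for c in classes], dtype=float)
        lfc[:, j] = pat * config.effect_size_lfc
    mean = base[:, None] * (2.0 ** lfc) * sf[None, :]
    gene_counts = pd.DataFrame(_nb_draw(rng, mean, alpha[:, None]),
                               index=pd.Index(gene_ids, name="feature_id"),
                               columns=design["sample_id"].to_numpy())

    # --- accessibility peaks -------------------------------------------------
    peak_ids = [f"peak{i:05d}" for i in range(config.n_peaks)]
    pclasses = _draw_classes(rng, config.n_peaks, config.peak_class_fractions, PEAK_CLASSES)
    truth.peak_class = dict(zip(peak_ids, (str(c) for c in pclasses)))
    motifs = list(config.motif_betas)
    # Causal motifs are enriched in their home class (the activator's sites
    # in irreversibly opened peaks, the repressor's in decreased peaks), so
    # motif counts carry the class-level accessibility signal as in tissue.
    rates = np.full((config.n_peaks, len(motifs)), config.motif_count_rate)
    for k, m in enumerate(motifs):
        home = MOTIF_HOME_CLASS.get(m)
        if home is not None:
            rates[np.asarray(pclasses) == home, k] = config.motif_class_rate
    mcounts = rng.poisson(rates)
    truth.peak_motif_counts = {
        pid: {m: int(mcounts[i, k]) for k, m in enumerate(motifs)}
        for i, pid in enumerate(peak_ids)
    }
    motif_effect = mcounts @ np.array([config.motif_betas[m] for m in motifs])

    plo, phi = config.peak_base_mean_log_range
    pbase = 10.0 ** rng.uniform(plo, phi, size=config.n_peaks)
    palpha = rng.gamma(config.dispersion_shape,
                       config.dispersion / config.dispersion_shape, size=config.n_peaks)
    palpha = np.clip(palpha, 1e-6, None)
    plfc = np.zeros((config.n_peaks, n_samp))
    truth.peak_effect = {}
    per_cond_effect = {}
    for cond in ("constant", "transient_d11"):
        pat = np.array([PEAK_PATTERNS[c][cond] for c in pclasses], dtype=float)
        per_cond_effect[cond] = pat * config.peak_effect_size_lfc + motif_effect
    for i, pid in enumerate(peak_ids):
        truth.peak_effect[pid] = {c: float(per_cond_effect[c][i]) for c in per_cond_effect}
    for j in range(n_samp):
        if is_kd[j] and cond_label[j] in per_cond_effect:
            plfc[:, j] = per_cond_effect[cond_label[j]]
    pmean = pbase[:, None] * (2.0 ** plfc) * sf[None, :]
    peak_counts = pd.DataFrame(_nb_draw(rng, pmean, palpha[:, None]),
                               index=pd.Index(peak_ids, name="feature_id"),
                               columns=design["sample_id"].to_numpy())
    return gene_counts, peak_counts, design, truth


# ---------------------------------------------------------------------------
# annotation: gene models, domains, peak calls, PWMs, window sequences

def _place_intervals(rng, chrom_lengths: dict, lengths: np.ndarray, spacing: int = 1000):
    """Place intervals non-overlapping with a minimum spacing, round-robin
    across chromosomes, at jittered positions."""
    chroms = sorted(chrom_lengths)
    cursors = {c: 0 for c in chroms}
    placements = []
    order = list(range(len(lengths)))
    for i in order:
        # pick the chromosome with the most room left
        c = max(chroms, key=lambda ch: chrom_lengths[ch] - cursors[ch])
        start = cursors[c] + spacing + int(rng.integers(0, spacing))
        end = start + int(lengths[i])
        if end > chrom_lengths[c]:
            raise ValueError("ran out of genome space; increase chrom_lengths")
        placements.append((c, start, end))
        cursors[c] = end
    return placements


def simulate_annotation(config: SimulationConfig, truth: SyntheticTruth):
    """Gene models, repressive domains, per-replicate peak calls, PWMs, windows.

    Polycomb-target genes (sampled per class at ``pcg_target_rate``) are
    fully covered by a planted domain (truth flag recomputable by the >=50%
    body-overlap rule); non-targets are never overlapped.  Confident peak
    calls pass the consolidation thresholds in both replicates and the
    merged set; noise peaks fail at least one criterion chosen uniformly.
    Accessibility windows (peak centre ±250 bp) carry the planted number of
    consensus occurrences of each causal motif.
    """
    config.validate()
    streams = config.streams()
    rng = streams["annotation"]
    seq_rng = streams["sequences"]
    gene_ids = sorted(truth.gene_class) or [f"gene{i:05d}" for i in range(config.n_genes)]
    if not truth.gene_class:
        truth.gene_class = {g: "unaffected" for g in gene_ids}

    # --- gene placement ------------------------------------------------------
    lengths = rng.integers(1000, 5001, size=len(gene_ids))
    placements = _place_intervals(rng, config.chrom_lengths, lengths, spacing=1000)
    strands = rng.choice(["+", "-"], size=len(gene_ids))
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": [p[0] for p in placements],
        "start": [p[1] for p in placements],
        "end": [p[2] for p in placements],
        "strand": strands,
    })
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)

    # --- repressive domains over Polycomb targets ----------------------------
    is_target = {}
    for g in gene_ids:
        rate = config.pcg_target_rate.get(truth.gene_class[g], 0.1)
        is_target[g] = bool(rng.random() < rate)
    truth.pcg_target = is_target
    dom_rows = []
    for row in genes.itertuples():
        if is_target[row.gene_id]:
            dom_rows.append((row.chrom, max(0, row.start - 400), row.end + 400))
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])
    from .intervals import merge_intervals
    domains = merge_intervals(domains, gap=0)

    # --- replicate peak calls for the consolidation rule ----------------------
    n_calls = config.n_confident_peaks + config.n_noise_peaks
    call_lengths = rng.integers(200, 801, size=n_calls)
    # Peak calls go on a dedicated spare chromosome so they never collide
    # with genes; consolidation only looks at the three call sets anyway.
    spare = {"callspace": max(10_000_000, n_calls * 3000)}
    call_pos = _place_intervals(rng, spare, call_lengths, spacing=500)
    confident = [f"conf{i:04d}" for i in range(config.n_confident_peaks)]
    noise = [f"noise{i:04d}" for i in range(config.n_noise_peaks)]
    names = confident + noise
    truth.confident_peaks = confident
    truth.noise_peaks = noise

    def _passing_rep(q_hi=0.04):
        return float(rng.uniform(0.2, 5.0)), float(10 ** rng.uniform(-10, np.log10(q_hi)))

    rep1_rows, rep2_rows, merged_rows = [], [], []
    failure_modes = rng.integers(0, 4, size=config.n_noise_peaks)
    for i, name in enumerate(names):
        chrom, start, end = call_pos[i]
        e1, q1 = _passing_rep()
        e2, q2 = _passing_rep()
        em = float(rng.uniform(2.2, 8.0))
        qm = float(10 ** rng.uniform(-10, -3))
        if name in noise:
            mode = failure_modes[i - config.n_confident_peaks]
            if mode == 0:       # absent from one replicate
                e1, q1 = None, None
            elif mode == 1:     # replicate q fails
                q2 = float(rng.uniform(0.05, 0.5))
            elif mode == 2:     # merged enrichment fails
                em = float(rng.uniform(0.0, 2.0))
            else:               # merged q fails
                qm = float(rng.uniform(0.01, 0.5))
        if e1 is not None:
            rep1_rows.append((chrom, start, end, name, e1, q1, "rep1"))
        rep2_rows.append((chrom, start, end, name, e2, q2, "rep2"))
        merged_rows.append((chrom, start, end, name, em, qm, "merged"))
    cols = ["chrom", "start", "end", "name", "enrichment", "qvalue", "replicate"]
    peak_calls = {
        "rep1": pd.DataFrame(rep1_rows, columns=cols),
        "rep2": pd.DataFrame(rep2_rows, columns=cols),
        "merged": pd.DataFrame(merged_rows, columns=cols),
    }

    # --- PWMs and window sequences -------------------------------------------
    bg = np.array([0.29, 0.21, 0.21, 0.29])  # AT-rich fly-like background
    pwms = []
    for motif, consensus in CAUSAL_CONSENSUS.items():
        if motif in config.motif_betas:
            pwms.append((motif, _consensus_pwm(consensus)))
    for k in range(config.n_decoy_motifs):
        L = int(seq_rng.integers(6, 11))
        consensus = "".join("ACGT"[b] for b in seq_rng.integers(0, 4, size=L))
        pwms.append((f"decoy{k:02d}", _consensus_pwm(consensus)))

    window = 2 * config.window_flank
    peak_ids = sorted(truth.peak_class) if truth.peak_class else []
    windows = {}
    for pid in peak_ids:
        seq = _random_seq(seq_rng, window, bg)
        occupied = []
        for motif, consensus in CAUSAL_CONSENSUS.items():
            count = truth.peak_motif_counts.get(pid, {}).get(motif, 0)
            for _ in range(count):
                seq = _plant(seq_rng, seq, consensus, occupied)
        windows[pid] = seq
    return genes, domains, peak_calls, pwms, windows, bg


def _consensus_pwm(consensus: str, strength: float = 0.94) -> np.ndarray:
    mat = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = strength
    return mat


def _random_seq(rng, length: int, bg: np.ndarray) -> str:
    return "".join("ACGT"[b] for b in rng.choice(4, size=length, p=bg))


def _plant(rng, seq: str, consensus: str, occupied: list) -> str:
    """Insert one consensus occurrence at a position not overlapping others."""
    L = len(consensus)
    for _ in range(200):
        pos = int(rng.integers(0, len(seq) - L + 1))
        if all(pos + L <= s or pos >= e for s, e in occupied):
            occupied.append((pos, pos + L))
            return seq[:pos] + consensus + seq[pos + L:]
    return seq  # window saturated; drop the extra occurrence


# ---------------------------------------------------------------------------
# motif regression fixture

def simulate_motif_regression(n_peaks: int = 1000, n_motifs: int = 50,
                              betas: dict | None = None, sigma: float = 0.5,
                              count_rate: float = 0.5, seed: int = 0):
    """Motif-count matrix plus two linear responses with planted effects.

    ``betas`` maps causal motif names to per-count effects (default
    Stat92E +0.5, zfh1 -0.5); the remaining motifs are inert.  Both the
    constant and transient responses share the planted effects with
    independent Gaussian noise of scale ``sigma``.
    """
    betas = dict(betas) if betas is not None else {"Stat92E": 0.5, "zfh1": -0.5}
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    names = list(betas) + [f"decoy{k:02d}" for k in range(n_motifs - len(betas))]
    X = rng.poisson(count_rate, size=(n_peaks, n_motifs))
    beta_vec = np.array([betas.get(m, 0.0) for m in names])
    signal = X @ beta_vec
    y_const = signal + rng.normal(0, sigma, size=n_peaks)
    y_trans = signal + rng.normal(0, sigma, size=n_peaks)
    counts = pd.DataFrame(X, columns=names,
                          index=[f"peak{i:05d}" for i in range(n_peaks)])
    return counts, y_const, y_trans, betas


# ---------------------------------------------------------------------------
# variants

def simulate_variants(config: SimulationConfig, truth: SyntheticTruth | None = None):
    """Per-sample somatic variant table with planted sharing structure.

    Most variants are private to one sample with Beta-distributed allele
    fractions concentrated below 0.2; ``variant_shared_count`` SNV keys are
    planted in >=2 tumour samples; a handful of SVs and CNVs carry their
    type-specific evidence fields.
    """
    config.validate()
    rng = config.streams()["variants"]
    truth = truth if truth is not None else SyntheticTruth()
    tumours = [f"T{i:02d}" for i in range(1, config.n_tumour_samples + 1)]
    controls = [f"C{i:02d}" for i in range(1, config.n_control_samples + 1)]
    if len(tumours) < 2 or len(controls) < 1:
        raise ValueError("need >=2 tumour samples and >=1 control sample")
    chroms = sorted(config.chrom_lengths)
    a, b = config.af_beta_params
    feat_cats = ["exon", "intron", "UTR", "intergenic", "other"]
    feat_probs = [0.15, 0.45, 0.08, 0.30, 0.02]

    used_pos = set()

    def _new_key():
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                break
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        return chrom, pos, str(ref), str(alt)

    def _af():
        x = float(rng.beta(a, b))
        return min(max(x, 1e-6), 1.0)

    rows = []
    carriers = {}
    for sample in tumours + controls:
        n_priv = int(rng.poisson(config.variant_private_rate))
        for _ in range(n_priv):
            chrom, pos, ref, alt = _new_key()
            vtype = "SNV" if rng.random() < 0.85 else "InDel"
            if vtype == "InDel":
                alt = alt + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            feat = str(rng.choice(feat_cats, p=feat_probs))
            rows.append((sample, chrom, pos, ref, alt, vtype, _af(),
                         np.nan, np.nan, feat, bool(rng.random() < 0.05)))
            if sample in tumours:
                carriers[f"{chrom}:{pos}:{ref}:{alt}"] = [sample]
        # a few SVs and CNVs per sample
        for _ in range(int(rng.poisson(3))):
            chrom, pos, ref, alt = _new_key()
            rows.append((sample, chrom, pos, ref, "<SV>", "SV", np.nan,
                         int(rng.integers(1, 12)), np.nan,
                         str(rng.choice(feat_cats, p=feat_probs)), False))
        for _ in range(int(rng.poisson(2))):
            chrom, pos, ref, alt = _new_key()
            ratio = float(np.exp(rng.normal(0.0, 0.5)))
            rows.append((sample, chrom, pos, ref, "<CNV>", "CNV", np.nan,
                         np.nan, ratio, str(rng.choice(feat_cats, p=feat_probs)), False))

    for _ in range(config.variant_shared_count):
        chrom, pos, ref, alt = _new_key()
        k = int(rng.integers(2, len(tumours) + 1))
        picked = sorted(rng.choice(tumours, size=k, replace=False))
        feat = str(rng.choice(feat_cats, p=feat_probs))
        af = _af()
        for sample in picked:
            rows.append((sample, chrom, pos, ref, alt, "SNV", af,
                         np.nan, np.nan, feat, False))
        carriers[f"{chrom}:{pos}:{ref}:{alt}"] = list(picked)

    truth.variant_carriers = carriers
    variants = pd.DataFrame(rows, columns=eio.VARIANT_COLUMNS)
    bad = variants["allele_fraction"].notna() & (
        (variants["allele_fraction"] <= 0) | (variants["allele_fraction"] > 1))
    if bad.any():
        raise ValueError("allele fraction outside (0, 1]")
    return variants, tumours, controls, truth


# ---------------------------------------------------------------------------
# bundle

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    gene_counts: pd.DataFrame
    peak_counts: pd.DataFrame
    design: pd.DataFrame
    genes: pd.DataFrame
    domains: pd.DataFrame
    peak_calls: dict
    pwms: list
    windows: dict
    background: np.ndarray
    variants: pd.DataFrame
    tumour_samples: list
    control_samples: list
    truth: SyntheticTruth


def simulate_cohort(config: SimulationConfig, outdir=None) -> SimulatedCohort:
    """Run every generator from one seed; optionally write all files."""
    truth = SyntheticTruth()
    gene_counts, peak_counts, design, truth = simulate_counts(config, truth)
    genes, domains, peak_calls, pwms, windows, bg = simulate_annotation(config, truth)
    variants, tumours, controls, truth = simulate_variants(config, truth)
    cohort = SimulatedCohort(config, gene_counts, peak_counts, design, genes,
                             domains, peak_calls, pwms, windows, bg, variants,
                             tumours, controls, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        eio.write_counts(gene_counts, outdir / "gene_counts.tsv")
        eio.write_counts(peak_counts, outdir / "peak_counts.tsv")
        eio.write_design(design, outdir / "design.tsv")
        eio.write_gene_annotation(genes, outdir / "genes.tsv")
        eio.write_bed(domains.assign(name="H3K27me3_domain", strand="."),
                      outdir / "h3k27me3_domains.bed")
        for rep, df in peak_calls.items():
            eio.write_narrowpeak(df, outdir / f"peakcalls_{rep}.tsv")
        eio.write_pwms(pwms, outdir / "motifs.txt")
        eio.write_fasta(windows, outdir / "peak_windows.fa")
        eio.write_variants(variants, outdir / "variants.tsv")
        truth.to_json(outdir / "truth.json")
    return cohort
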