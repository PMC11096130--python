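"""Multi-layer self-organizing maps and reversibility classification.

The central classification device: differential features are selected,
their log2 fold changes clipped at the 5th/95th percentiles, and clustered
with a batch-trained multi-layer SOM on a small hexagonal (optionally
toroidal) grid.  Grid units are then labelled by the sign pattern of their
codebook means: genes (3x2 grid, two layers: constant KD; transient KD d9+
d11) become irreversible / reversible / transient-specific / down1-3, and
accessibility peaks (1x3 grid, four layers: two LFC layers plus two
-log10 padj layers) become irreversible / reversible / decreased.

Training choices (the upstream tooling does not print its defaults, so
these are frozen here): batch algorithm, 100 epochs, Gaussian
neighbourhood whose radius decays linearly from 2/3 of the maximal grid
distance to 0, codebooks initialized from a seeded sample of data rows
drawn from a canonical (lexicographically sorted) row ordering so results
do not depend on input row order.  Each layer is scaled by its total
variance before weighting ("similar weights" across layers); nearest-unit
ties break to the lowest unit index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HexGrid",
    "SOMModel",
    "train_supersom",
    "select_de_genes",
    "clip_percentiles",
    "label_gene_clusters",
    "select_and_cluster_atac",
    "label_units_genes",
    "label_units_atac",
]

GENE_PADJ = 0.05
GENE_LFC = 1.0
ATAC_PADJ = 1e-3
ATAC_LFC = 1.0
ATAC_LOG10_BASEMEAN = 1.25
NEGLOG10_CAP = 20.0
DEFAULT_EPOCHS = 100
LABEL_DELTA = 0.5  # log2 units separating "changed" from "flat" codebook means

GENE_CLUSTERS = ["irreversible", "reversible", "transient-specific",
                 "down1", "down2", "down3", "unaffected"]


class HexGrid:
    """Hexagonal unit layout with optional toroidal wrap-around.

    Units are indexed row-major on an ``n_y`` x ``n_x`` grid; odd rows are
    offset by half a unit and rows are sqrt(3)/2 apart, so horizontal
    neighbours are at distance 1.  On a torus, distances are minimized over
    the nine wrapped copies of the plane.
    """

    def __init__(self, n_x: int, n_y: int, toroidal: bool = True):
        if n_x < 1 or n_y < 1 or n_x * n_y < 2:
            raise ValueError("grid needs at least 2 units")
        self.n_x, self.n_y, self.toroidal = n_x, n_y, toroidal
        cols, rows = np.meshgrid(np.arange(n_x), np.arange(n_y))
        x = cols + 0.5 * (rows % 2)
        y = rows * np.sqrt(3) / 2
        self.coords = np.column_stack([x.ravel(), y.ravel()])

    @property
    def n_units(self) -> int:
        return self.n_x * self.n_y

    def distances(self) -> np.ndarray:
        c = self.coords
        if not self.toroidal:
            diff = c[:, None, :] - c[None, :, :]
            return np.sqrt((diff ** 2).sum(axis=-1))
        wx = self.n_x
        wy = self.n_y * np.sqrt(3) / 2
        best = None
        for dx in (-wx, 0, wx):
            for dy in (-wy, 0, wy):
                shifted = c + np.array([dx, dy])
                diff = shifted[:, None, :] - c[None, :, :]
                d = np.sqrt((diff ** 2).sum(axis=-1))
                best = d if best is None else np.minimum(best, d)
        return best


@dataclass
class SOMModel:
    grid: HexGrid
    layers: list                      # per-layer codebooks, units x layer-dims (original units)
    layer_weights: np.ndarray         # user weights, one per layer
    layer_scales: np.ndarray          # 1/total-variance scaling applied in distances
    assignment: np.ndarray            # feature -> unit index
    quantization_error: float
    feature_ids: list = field(default_factory=list)

    def unit_means(self) -> list:
        """Per-unit codebook vectors, one array (units x dims) per layer."""
        return [np.asarray(c) for c in self.layers]


def _layer_scales(layers) -> np.ndarray:
    scales = []
    for X in layers:
        tv = float(np.sum(np.var(X, axis=0)))
        scales.append(1.0 / tv if tv > 0 else 1.0)
    return np.array(scales)


def _weighted_dist2(layers, codebooks, weights) -> np.ndarray:
    """features x units weighted squared distance, sum_l w_l ||x-c||^2 / sum w."""
    n = layers[0].shape[0]
    u = codebooks[0].shape[0]
    d2 = np.zeros((n, u))
    for X, C, w in zip(layers, codebooks, weights):
        sq = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=-1)
        d2 += w * sq
    return d2 / weights.sum()


def batch_update(layers, codebooks, bmu: np.ndarray, neighborhood: np.ndarray):
    """One batch SOM step: neighbourhood-weighted means of assigned rows.

    ``neighborhood`` is the units x units kernel matrix H; the new codebook
    of unit u is sum_i H[u, bmu_i] x_i / sum_i H[u, bmu_i].  Units with zero
    total weight keep their previous codebook.  Duplicating every data row
    leaves the update unchanged.
    """
    n_units = codebooks[0].shape[0]
    onehot = np.zeros((len(bmu), n_units))
    onehot[np.arange(len(bmu)), bmu] = 1.0
    mass = neighborhood @ onehot.sum(axis=0)          # units
    new = []
    for X, C in zip(layers, codebooks):
        num = neighborhood @ (onehot.T @ X)           # units x dims
        with np.errstate(invalid="ignore"):
            upd = num / mass[:, None]
        new.append(np.where(mass[:, None] > 0, upd, C))
    return new


def train_supersom(layers: list, grid: HexGrid, seed: int = 0,
                   epochs: int = DEFAULT_EPOCHS, weights=None,
                   feature_ids=None, n_starts: int = 5) -> SOMModel:
    """Batch-train a multi-layer SOM.

    ``layers`` is a list of (features x dims) arrays sharing their row
    order.  Rows with missing values are rejected.  Training runs
    ``n_starts`` times with seeded initializations and progressively
    shorter neighbourhood phases (the last start is plain batch k-means
    from the farthest-point init); the map with the lowest quantization
    error wins.  The full-schedule SOM is topology-faithful but on small
    grids its cooling phase can strand a unit between well-separated
    clusters, a local optimum the radius-zero refinement cannot leave;
    the shorter schedules escape it and QE arbitrates.  Returns the
    trained model with per-feature unit assignments and the mean weighted
    squared distance of features to their unit (quantization error).
    """
    n_starts = max(1, n_starts)
    best = None
    for s in range(n_starts):
        sub_seed = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, s])
        radius_factor = 1.0 - s / n_starts
        model = _train_once(layers, grid, sub_seed, epochs, weights,
                            feature_ids, radius_factor)
        if best is None or model.quantization_error < best.quantization_error:
            best = model
        if epochs == 0:
            break  # no training: the first init defines the model
    return best


def _train_once(layers, grid, seed_seq, epochs, weights, feature_ids,
                radius_factor: float = 1.0) -> SOMModel:
    layers = [np.asarray(X, dtype=float) for X in layers]
    n = layers[0].shape[0]
    for X in layers:
        if X.shape[0] != n:
            raise ValueError("all layers must have the same number of rows")
        if not np.isfinite(X).all():
            raise ValueError("rows with missing values are not allowed")
    if weights is None:
        weights = np.ones(len(layers))
    weights = np.asarray(weights, dtype=float)
    scales = _layer_scales(layers)
    eff = weights * scales

    # Canonical row order makes the seeded init invariant to input row order.
    stacked = np.hstack(layers)
    canonical = np.lexsort(stacked.T[::-1])
    order_pos = np.empty(n, dtype=np.int64)
    order_pos[canonical] = np.arange(n)
    rng = np.random.default_rng(seed_seq)
    k = grid.n_units
    # Farthest-point init: one seeded pick, then greedy maximin picks in the
    # weighted distance metric.  Purely random picks routinely start two
    # units inside one cluster on tiny grids, which batch training cannot
    # always undo (a dead-unit configuration).
    S = np.hstack([X * np.sqrt(w) for X, w in zip(layers, eff)])
    picks = [int(canonical[int(rng.integers(n))])]
    d2min = ((S - S[picks[0]]) ** 2).sum(axis=1)
    while len(picks) < k:
        best = int(np.lexsort((order_pos, -d2min))[0])
        picks.append(best)
        d2min = np.minimum(d2min, ((S - S[best]) ** 2).sum(axis=1))
    codebooks = [X[picks].copy() for X in layers]

    dist = grid.distances()
    r0 = (2.0 / 3.0) * dist.max() * radius_factor
    for t in range(epochs):
        radius = r0 * (1.0 - t / epochs)
        if radius > 1e-9:
            H = np.exp(-(dist ** 2) / (2.0 * radius ** 2))
        else:
            H = np.eye(k)
        d2 = _weighted_dist2(layers, codebooks, eff)
        bmu = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        codebooks = batch_update(layers, codebooks, bmu, H)

    if epochs > 0:
        # Radius-zero refinement with dead-unit rescue: the shrinking
        # neighbourhood can strand a unit between well-separated clusters;
        # a stranded (empty) unit is re-seeded on the worst-quantized row
        # (ties broken canonically), which never increases the quantization
        # error, then plain batch (k-means-like) iterations run to a fix
        # point.  epochs=0 means "no training" and skips this too.
        H = np.eye(k)
        for _ in range(50):
            d2 = _weighted_dist2(layers, codebooks, eff)
            bmu = d2.argmin(axis=1)
            err = d2[np.arange(n), bmu]
            moved = False
            for u in range(k):
                if not (bmu == u).any():
                    far = int(np.lexsort((order_pos, -err))[0])
                    for X, C in zip(layers, codebooks):
                        C[u] = X[far]
                    err[far] = -np.inf
                    moved = True
            if moved:
                d2 = _weighted_dist2(layers, codebooks, eff)
                bmu = d2.argmin(axis=1)
            new_codebooks = batch_update(layers, codebooks, bmu, H)
            changed = any(not np.array_equal(a, b)
                          for a, b in zip(new_codebooks, codebooks))
            codebooks = new_codebooks
            if not changed and not moved:
                break

    d2 = _weighted_dist2(layers, codebooks, eff)
    bmu = d2.argmin(axis=1)
    qe = float(d2[np.arange(n), bmu].mean())
    return SOMModel(grid=grid, layers=codebooks, layer_weights=weights,
                    layer_scales=scales, assignment=bmu, quantization_error=qe,
                    feature_ids=list(feature_ids) if feature_ids is not None else [])


# ---------------------------------------------------------------------------
# selection and clipping

def _sig_mask(res: pd.DataFrame, padj_cut: float, lfc_cut: float) -> pd.Series:
    padj = res["padj"]
    return (padj.notna() & (padj < padj_cut)
            & (res["log2FoldChange"].abs() > lfc_cut))


def select_de_genes(results: dict, control_contrast: pd.DataFrame,
                    padj_cut: float = GENE_PADJ, lfc_cut: float = GENE_LFC) -> pd.DataFrame:
    """Select differential genes and build their LFC matrix.

    ``results`` maps contrast names ("constant", "transient_d9",
    "transient_d11") to differential result frames over a shared feature
    universe.  A gene is kept when significant (padj < cut and |LFC| > cut)
    in any of those contrasts AND not significant in the control
    (no-perturbation vs control) contrast.  Returns an LFC matrix indexed by
    gene with one column per contrast.
    """
    names = list(results)
    frames = {k: v.set_index("feature_id") for k, v in results.items()}
    ctrl = control_contrast.set_index("feature_id")
    universe = frames[names[0]].index
    for k, f in frames.items():
        if not universe.equals(f.index):
            raise ValueError(f"contrast {k!r} has mismatched feature ids")
    if not universe.equals(ctrl.index):
        raise ValueError("control contrast has mismatched feature ids")

    sig_any = pd.Series(False, index=universe)
    for f in frames.values():
        sig_any |= _sig_mask(f, padj_cut, lfc_cut)
    sig_ctrl = _sig_mask(ctrl, padj_cut, lfc_cut)
    selected = universe[sig_any & ~sig_ctrl]
    lfc = pd.DataFrame({k: frames[k].loc[selected, "log2FoldChange"] for k in names})
    lfc.index.name = "feature_id"
    return lfc


def clip_percentiles(matrix: pd.DataFrame, lower: float = 5.0, upper: float = 95.0) -> pd.DataFrame:
    """Clip each column at its own empirical percentiles (linear interpolation)."""
    if len(matrix) == 0:
        raise ValueError("empty matrix")
    out = matrix.copy()
    for col in out.columns:
        lo, hi = np.percentile(out[col], [lower, upper])
        out[col] = out[col].clip(lo, hi)
    return out


# ---------------------------------------------------------------------------
# unit labelling

def _nearest_gene_rule(cm: float, tm: float, delta: float) -> str:
    """Distance of a codebook-mean pair to each idealized sign pattern."""
    patterns = {
        "irreversible": (1, 1), "reversible": (1, 0), "transient-specific": (0, 1),
        "down-both": (-1, -1), "down-constant": (-1, 0), "down-transient": (0, -1),
        "unaffected": (0, 0),
    }
    best, best_d = None, np.inf
    for name, (pc, pt) in patterns.items():
        d = (cm - 2 * delta * pc) ** 2 + (tm - 2 * delta * pt) ** 2
        if d < best_d:
            best, best_d = name, d
    return best


def label_units_genes(constant_means: np.ndarray, transient_means: np.ndarray,
                      delta: float = LABEL_DELTA) -> list:
    """Label SOM units by their codebook means on the two LFC layers.

    Sign rules: constant>+d & transient>+d -> irreversible; constant>+d &
    |transient|<=d -> reversible; |constant|<=d & transient>+d ->
    transient-specific.  Mirrored negative patterns are down-clusters,
    ordered down1..down3 by ascending constant-layer mean.  A unit matching
    no rule is labelled by the nearest rule with a warning.
    """
    raw = []
    for cm, tm in zip(constant_means, transient_means):
        if cm > delta and tm > delta:
            lab = "irreversible"
        elif cm > delta and abs(tm) <= delta:
            lab = "reversible"
        elif abs(cm) <= delta and tm > delta:
            lab = "transient-specific"
        elif cm < -delta and tm < -delta:
            lab = "down-both"
        elif cm < -delta and abs(tm) <= delta:
            lab = "down-constant"
        elif abs(cm) <= delta and tm < -delta:
            lab = "down-transient"
        elif abs(cm) <= delta and abs(tm) <= delta:
            lab = "unaffected"
        else:
            lab = _nearest_gene_rule(cm, tm, delta)
            warnings.warn(
                f"ambiguous SOM unit (constant={cm:.2f}, transient={tm:.2f}); "
                f"labelled by nearest rule {lab!r}")
        raw.append(lab)
    # Down-units get ordinal names by ascending constant-layer mean.
    down_units = [i for i, lab in enumerate(raw) if lab.startswith("down")]
    order = sorted(down_units, key=lambda i: (constant_means[i], i))
    labels = list(raw)
    for rank, i in enumerate(order, start=1):
        labels[i] = f"down{rank}"
    return labels


def label_gene_clusters(model: SOMModel, lfc_matrix: pd.DataFrame,
                        delta: float = LABEL_DELTA) -> pd.DataFrame:
    """Map selected genes to cluster labels through their SOM unit.

    Layer 1 holds the constant-KD LFC; layer 2 holds the transient-KD LFC
    columns (d9 and d11), summarized by their mean per unit.
    """
    cmeans = model.layers[0].mean(axis=1)
    tmeans = model.layers[1].mean(axis=1)
    unit_labels = label_units_genes(cmeans, tmeans, delta=delta)
    clusters = [unit_labels[u] for u in model.assignment]
    return pd.DataFrame({"feature_id": lfc_matrix.index, "cluster": clusters})


def label_units_atac(constant_means: np.ndarray, transient_means: np.ndarray,
                     delta: float = LABEL_DELTA) -> list:
    """Three-unit ATAC labelling: decreased / irreversible / reversible."""
    labels = []
    for cm, tm in zip(constant_means, transient_means):
        if cm < 0 and tm <= 0:
            labels.append("decreased")
        elif tm > delta:
            labels.append("irreversible")
        else:
            labels.append("reversible")
    return labels


def select_and_cluster_atac(res_constant: pd.DataFrame, res_transient: pd.DataFrame,
                            seed: int = 0, epochs: int = DEFAULT_EPOCHS,
                            padj_cut: float = ATAC_PADJ, lfc_cut: float = ATAC_LFC,
                            min_log10_basemean: float = ATAC_LOG10_BASEMEAN,
                            delta: float = LABEL_DELTA):
    """Select differential accessibility peaks and cluster them on a 1x3 grid.

    Selection: significant (padj < 1e-3 and |LFC| > 1) after constant or
    transient KD AND log10(baseMean) >= 1.25.  Four layers enter the SOM:
    the two clipped LFC vectors and the two padj vectors transformed to
    -log10(padj) capped at 20 (raw padj is bounded and skewed; the cap and
    transform are this package's declared choice).  Returns
    (classification frame, SOMModel).
    """
    rc = res_constant.set_index("feature_id")
    rt = res_transient.set_index("feature_id")
    if not rc.index.equals(rt.index):
        raise ValueError("constant and transient contrasts have mismatched feature ids")
    sig = _sig_mask(rc, padj_cut, lfc_cut) | _sig_mask(rt, padj_cut, lfc_cut)
    base = rc["baseMean"].where(rc["baseMean"] > 0, np.nan)
    expressed = np.log10(base) >= min_log10_basemean
    selected = rc.index[sig & expressed.fillna(False)]
    if len(selected) < 3:
        raise ValueError(f"only {len(selected)} peaks selected; cannot fill a 1x3 grid")

    lfc = clip_percentiles(pd.DataFrame({
        "constant": rc.loc[selected, "log2FoldChange"],
        "transient": rt.loc[selected, "log2FoldChange"],
    }))
    neglog = pd.DataFrame({
        "constant": -np.log10(rc.loc[selected, "padj"].fillna(1.0).clip(lower=10 ** -NEGLOG10_CAP)),
        "transient": -np.log10(rt.loc[selected, "padj"].fillna(1.0).clip(lower=10 ** -NEGLOG10_CAP)),
    }).clip(upper=NEGLOG10_CAP)

    layers = [
        lfc[["constant"]].to_numpy(), lfc[["transient"]].to_numpy(),
        neglog[["constant"]].to_numpy(), neglog[["transient"]].to_numpy(),
    ]
    grid = HexGrid(1, 3, toroidal=True)
    model = train_supersom(layers, grid, seed=seed, epochs=epochs,
                           feature_ids=list(selected))
    unit_labels = label_units_atac(model.layers[0][:, 0], model.layers[1][:, 0], delta=delta)
    classification = pd.DataFrame({
        "peak": selected,
        "cluster": [unit_labels[u] for u in model.assignment],
    })
    return classification, model
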