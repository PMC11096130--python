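"""PWM scanning and the motif-count regression on accessibility changes.

Motif occurrences are counted in fixed windows around peak centres
(±250 bp) with log-odds scores thresholded at an exact match p-value
(default 5e-4) computed by dynamic programming over the background score
distribution.  Motif counts then feed a two-stage regression: L1-penalized
(LASSO) fits over a fixed lambda grid predict the log2 accessibility fold
changes after constant and transient perturbation, the 25 motifs with the
strongest absolute coefficients in either model are refit by OLS, and
motifs with a coefficient significant at p < 1e-5 in at least one linear
model are reported as predictive.

Scores are discretized once, to 1e-3 log2-odds units, and both the
threshold DP and the scanner operate on the discretized scores, so the
threshold is exact for the scores actually used (no sequence above the
p-cutoff is ever admitted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "PWM",
    "pwm_threshold",
    "count_motif_hits",
    "fit_motif_effect_model",
    "motif_dose_response",
    "lambda_grid",
    "sequence_background",
]

PSEUDOCOUNT = 0.008
GRANULARITY = 1e-3        # log2-odds discretization step
DEFAULT_P_CUTOFF = 5e-4
WINDOW_FLANK = 250        # peak centre +/- this many bp
TOP_K = 25
SELECT_P = 1e-5
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on integer codes


def lambda_grid() -> np.ndarray:
    """The fixed L1 penalty grid 10^(2, 1.9, ..., -3)."""
    return 10.0 ** np.arange(2.0, -3.0 - 1e-9, -0.1)


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other character -> -1 (never matches)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def sequence_background(seqs) -> np.ndarray:
    """Nucleotide frequencies of a sequence collection ("bg = genome")."""
    counts = np.zeros(4)
    for s in seqs:
        enc = encode(s)
        for b in range(4):
            counts[b] += int((enc == b).sum())
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T bases in background sequences")
    return counts / total


@dataclass
class PWM:
    """A probability motif model with discretized log2-odds scores."""

    motif_id: str
    probs: np.ndarray        # positions x 4, rows sum to 1
    background: np.ndarray   # length-4 frequencies

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id!r} rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background frequencies must be strictly positive")
        corrected = (self.probs + PSEUDOCOUNT) / (1.0 + 4.0 * PSEUDOCOUNT)
        lo = np.log2(corrected / self.background[None, :])
        # integer milli-log2-odds; scanner and DP share this exact score space
        self.scores_int = np.round(lo / GRANULARITY).astype(np.int64)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores_int.max(axis=1).sum() * GRANULARITY)

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.motif_id = self.motif_id
        rc.probs = self.probs[::-1, ::-1].copy()
        rc.background = self.background
        rc.scores_int = self.scores_int[::-1][:, COMPLEMENT].copy()
        return rc


def _score_distribution(pwm: PWM):
    """Exact background distribution of the integer score by convolution.

    Returns (offset, probs) where probs[k] = P(score_int == offset + k).
    """
    mins = pwm.scores_int.min(axis=1)
    maxs = pwm.scores_int.max(axis=1)
    offset = int(mins.sum())
    size = int((maxs - mins).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    width = 1
    for pos in range(len(pwm)):
        lo = int(mins[pos])
        span = int(maxs[pos] - lo)
        new = np.zeros(width + span)
        for b in range(4):
            shift = int(pwm.scores_int[pos, b]) - lo
            new[shift:shift + width] += pwm.background[b] * dist[:width]
        dist[:width + span] = new
        width += span
    return offset, dist[:width]


def pwm_threshold(pwm: PWM, p_cutoff: float = DEFAULT_P_CUTOFF) -> float:
    """Smallest score s with background P(score >= s) <= ``p_cutoff``.

    Computed exactly on the discretized score distribution.  With
    ``p_cutoff=1`` this is the minimal attainable score.
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must be in (0, 1]")
    offset, dist = _score_distribution(pwm)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score_int >= offset + k)
    ok = np.nonzero((tail <= p_cutoff + 1e-15) & (dist > 0))[0]
    if len(ok) == 0:
        # nothing qualifies below the cutoff: threshold just above the max
        return float((offset + len(dist)) * GRANULARITY)
    # smallest *attained* score whose tail is within the cutoff
    return float((offset + int(ok[0])) * GRANULARITY)


def _window_scores(enc: np.ndarray, pwm: PWM) -> np.ndarray:
    """Integer score at every start position; -inf where any base is non-ACGT."""
    L = len(pwm)
    n = len(enc) - L + 1
    if n <= 0:
        return np.full(0, -np.inf)
    total = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for k in range(L):
        col = enc[k:k + n]
        good = col >= 0
        valid &= good
        total += np.where(good, pwm.scores_int[k, np.clip(col, 0, 3)], 0)
    return np.where(valid, total, -np.inf)


def _dedup_positions(positions: np.ndarray, scores: np.ndarray, length: int) -> list:
    """Collapse overlapping same-strand hits to the best-scoring one.

    Greedy left-to-right: within a chain of mutually overlapping hits the
    highest score wins (leftmost on ties).
    """
    kept = []
    best_pos, best_score, chain_end = None, -np.inf, -1
    for pos, score in zip(positions, scores):
        if best_pos is not None and pos < chain_end:
            if score > best_score:
                best_pos, best_score = pos, score
            chain_end = max(chain_end, pos + length)
        else:
            if best_pos is not None:
                kept.append(int(best_pos))
            best_pos, best_score, chain_end = pos, score, pos + length
    if best_pos is not None:
        kept.append(int(best_pos))
    return kept


def count_hits_in_sequence(seq: str, pwm: PWM, threshold: float) -> int:
    """Deduplicated two-strand hit count for one motif in one window.

    A start position matched on both strands counts once.  Windows shorter
    than the motif yield 0 with a warning.
    """
    enc = encode(seq)
    if len(enc) < len(pwm):
        warnings.warn(f"sequence shorter than motif {pwm.motif_id!r}; count 0")
        return 0
    thr_int = int(round(threshold / GRANULARITY))
    starts = set()
    for strand_pwm in (pwm, pwm.reverse_complement()):
        sc = _window_scores(enc, strand_pwm)
        idx = np.nonzero(sc >= thr_int)[0]
        starts.update(_dedup_positions(idx, sc[idx], len(pwm)))
    return len(starts)


def count_motif_hits(sequences: dict, pwms: list, background=None,
                     p_cutoff: float = DEFAULT_P_CUTOFF) -> pd.DataFrame:
    """Count motif occurrences in every window: peaks x motifs integer matrix.

    ``sequences`` maps window name -> sequence; ``pwms`` is a list of
    :class:`PWM` or (motif_id, matrix) pairs.  When ``background`` is None
    it is estimated from the windows themselves.
    """
    if background is None:
        background = sequence_background(sequences.values())
    pwm_objs = []
    for p in pwms:
        if isinstance(p, PWM):
            pwm_objs.append(p)
        else:
            motif_id, mat = p
            pwm_objs.append(PWM(motif_id, np.asarray(mat), background))
    thresholds = {p.motif_id: pwm_threshold(p, p_cutoff) for p in pwm_objs}
    data = {
        p.motif_id: [count_hits_in_sequence(seq, p, thresholds[p.motif_id])
                     for seq in sequences.values()]
        for p in pwm_objs
    }
    return pd.DataFrame(data, index=list(sequences), dtype=np.int64)


# ---------------------------------------------------------------------------
# two-stage regression

def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X, dtype=float)
    Z[:, keep] = (X[:, keep] - mean[keep]) / sd[keep]
    return Z, keep


def _cv_lasso(Z: np.ndarray, y: np.ndarray, seed: int):
    """5-fold CV over the fixed lambda grid; returns coefs at lambda.min."""
    lambdas = lambda_grid()
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    mse = np.zeros(len(lambdas))
    for train, test in kf.split(Z):
        for j, lam in enumerate(lambdas):
            model = Lasso(alpha=lam, fit_intercept=True, max_iter=5000, tol=1e-6)
            model.fit(Z[train], y[train])
            pred = model.predict(Z[test])
            mse[j] += float(((y[test] - pred) ** 2).mean())
    best = int(np.argmin(mse))
    final = Lasso(alpha=lambdas[best], fit_intercept=True, max_iter=20000, tol=1e-8)
    final.fit(Z, y)
    return final.coef_, float(lambdas[best])


def fit_motif_effect_model(counts: pd.DataFrame, lfc_constant, lfc_transient,
                           seed: int = 0, expressed_mask=None,
                           n_top: int = TOP_K, select_p: float = SELECT_P) -> pd.DataFrame:
    """Two-stage motif-effect model on accessibility fold changes.

    Stage 1: two LASSO regressions (constant and transient responses) on the
    standardized motif-count matrix, penalty chosen by seeded 5-fold CV over
    the fixed lambda grid.  Stage 2: the ``n_top`` motifs with the largest
    max(|coef_constant|, |coef_transient|) are refit by OLS; t values and
    two-sided p per model are reported, and ``selected`` flags motifs with
    p < ``select_p`` in at least one model.  Motifs whose LASSO coefficient
    is exactly 0 in both models never enter stage 2.

    ``expressed_mask`` optionally restricts the candidate motifs to those
    whose transcription factor passed expression filtering.
    """
    if expressed_mask is not None:
        counts = counts.loc[:, list(expressed_mask)]
    if len(counts) < 50:
        raise ValueError(f"need >=50 peaks for stable cross-validation, got {len(counts)}")
    y_const = np.asarray(lfc_constant, dtype=float)
    y_trans = np.asarray(lfc_transient, dtype=float)
    if len(y_const) != len(counts) or len(y_trans) != len(counts):
        raise ValueError("response lengths must match the count matrix rows")

    X = counts.to_numpy(dtype=float)
    Z, _ = _standardize(X)
    coef_c, lam_c = _cv_lasso(Z, y_const, seed)
    coef_t, lam_t = _cv_lasso(Z, y_trans, seed)

    out = pd.DataFrame({
        "motif": counts.columns,
        "coef_constant": coef_c,
        "coef_transient": coef_t,
    })
    out["strength"] = np.maximum(np.abs(coef_c), np.abs(coef_t))
    out[["t_constant", "t_transient", "p_constant", "p_transient"]] = np.nan
    out["selected"] = False

    candidates = out[out["strength"] > 0].sort_values(
        ["strength", "motif"], ascending=[False, True])
    top = candidates.head(n_top).index
    if len(top) > 0:
        cols = out.loc[top, "motif"].tolist()
        Ztop = sm.add_constant(Z[:, [counts.columns.get_loc(c) for c in cols]])
        for resp, tag in ((y_const, "constant"), (y_trans, "transient")):
            fit = sm.OLS(resp, Ztop).fit()
            out.loc[top, f"t_{tag}"] = fit.tvalues[1:]
            out.loc[top, f"p_{tag}"] = fit.pvalues[1:]
        out.loc[top, "selected"] = (
            (out.loc[top, "p_constant"] < select_p) | (out.loc[top, "p_transient"] < select_p))
    out.attrs["lambda_constant"] = lam_c
    out.attrs["lambda_transient"] = lam_t
    return out.drop(columns=["strength"]).reset_index(drop=True)


def motif_dose_response(lfc, counts, bins=(0, 1, 2, 3)) -> pd.DataFrame:
    """Per-motif-count summaries of peak fold changes plus Wilcoxon tests.

    ``bins`` gives the left edges of the count bins; the last is open-ended
    ("3+").  Each non-reference bin is compared against the 0-count bin with
    a two-sided Wilcoxon rank-sum test; empty bins are dropped with a
    warning.
    """
    from .enrichment import wilcoxon_ranksum

    lfc = np.asarray(lfc, dtype=float)
    counts = np.asarray(counts)
    edges = list(bins)
    rows = []
    ref = lfc[counts == edges[0]]
    for i, left in enumerate(edges):
        if i + 1 < len(edges):
            mask = (counts >= left) & (counts < edges[i + 1])
            label = str(left)
        else:
            mask = counts >= left
            label = f"{left}+"
        vals = lfc[mask]
        if vals.size == 0:
            warnings.warn(f"empty motif-count bin {label}; dropped")
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        if i == 0 or ref.size == 0:
            p = np.nan
        else:
            p = wilcoxon_ranksum(vals, ref)
        rows.append((label, int(vals.size), med, q1, q3, p))
    return pd.DataFrame(rows, columns=["bin", "n", "median", "q1", "q3", "p_vs_zero"])
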