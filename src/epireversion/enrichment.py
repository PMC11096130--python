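"""Over-representation statistics and rank-based group comparisons.

One-sided Fisher tests (hypergeometric upper tail) for gene-set enrichment
within clusters, Benjamini-Hochberg FDR, and the two-sided Wilcoxon
rank-sum test used for all group comparisons.  Gene sets come from the
caller (GMT-like files or in-memory dicts); no ontology database is
consulted here.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_greater",
    "bh_fdr",
    "overrepresentation_by_cluster",
    "wilcoxon_ranksum",
    "significance_tier",
]

# Figure-legend significance tiers for FDR values.
TIER_CUTOFFS = [(1e-5, "****"), (1e-3, "***"), (5e-2, "*")]

EXACT_WILCOXON_MAX_N = 12


def fisher_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided Fisher's exact test (alternative='greater') on a 2x2 table.

    Table layout: ``a`` = in-set & in-cluster, ``b`` = in-set & out,
    ``c`` = out-of-set & in-cluster, ``d`` = neither.  Returns
    ``(p, odds_ratio)`` where p is the exact hypergeometric upper tail
    P(X >= a) and the odds ratio is the sample OR with a Haldane 0.5
    correction when any cell is zero.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"contingency cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    # X ~ Hypergeom(N=n, K=a+b set members, n_draws=a+c cluster size)
    p = float(sps.hypergeom.sf(a - 1, n, a + b, a + c))
    if min(cells) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return min(p, 1.0), odds


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_tier(fdr: float) -> str:
    for cutoff, stars in TIER_CUTOFFS:
        if fdr < cutoff:
            return stars
    return "NS"


def overrepresentation_by_cluster(classification: pd.Series, gene_sets: dict,
                                  universe) -> pd.DataFrame:
    """One-sided Fisher test of every gene set against every cluster.

    ``classification`` maps feature -> cluster label over (a subset of) the
    universe; features outside the universe are ignored, and sets must be
    subsets of the universe.  All tests in one call form a single FDR family.
    """
    universe = list(dict.fromkeys(universe))
    if len(universe) == 0:
        raise ValueError("empty universe")
    uset = set(universe)
    classification = classification[classification.index.isin(uset)]
    clusters = sorted(classification.unique())
    rows = []
    for set_name, members in gene_sets.items():
        members = set(members)
        if not members <= uset:
            raise ValueError(f"gene set {set_name!r} is not a subset of the universe")
        for cluster in clusters:
            in_cluster = set(classification.index[classification == cluster])
            a = len(members & in_cluster)
            b = len(members) - a
            c = len(in_cluster) - a
            d = len(uset) - a - b - c
            p, odds = fisher_greater(a, b, c, d)
            rows.append((set_name, cluster, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["set", "cluster", "a", "b", "c", "d",
                                      "odds_ratio", "pvalue"])
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out["tier"] = [significance_tier(f) for f in out["fdr"]]
    return out


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of all rank splits.

    Valid with ties: mid-ranks are computed on the pooled sample and every
    C(n, n_x) assignment of the pooled ranks to the x-group is enumerated.
    Two-sided p = 2 * min(P(W <= w), P(W >= w)) capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = len(pooled), len(x)
    w_obs = ranks[:nx].sum()
    lo = hi = 0
    total = 0
    for comb in itertools.combinations(range(n), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_ranksum(x, y, alternative: str = "two-sided") -> float:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of all rank splits when the combined sample size is at
    most 12 (correct under ties); otherwise the normal approximation with
    tie correction and continuity correction.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size + y.size <= EXACT_WILCOXON_MAX_N:
        return _ranksum_exact(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
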