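"""Interval algebra, checked against per-base / all-pairs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from epireversion.intervals import (assign_peaks_to_tss, classify_pcg_targets,
                                    consolidate_peaks, gene_has_active_peak,
                                    merge_intervals, stitch_domains)

# ---------------------------------------------------------------------------
# oracles


def coverage_mask(intervals: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for row in intervals[intervals["chrom"] == chrom].itertuples():
        mask[row.start:row.end] = True
    return mask


def brute_pcg(genes, domains, length=100_000):
    flags = {}
    masks = {c: coverage_mask(domains, c, length) for c in genes["chrom"].unique()}
    for g in genes.itertuples():
        frac = masks[g.chrom][g.start:g.end].mean()
        flags[g.gene_id] = frac >= 0.5
    return flags


def brute_active(genes, peaks, upstream=2500, length=100_000):
    flags = {}
    masks = {c: coverage_mask(peaks, c, length + upstream + 1)
             for c in genes["chrom"].unique()}
    for g in genes.itertuples():
        if g.strand == "+":
            lo, hi = max(0, g.start - upstream), g.end
        else:
            lo, hi = g.start, g.end + upstream
        flags[g.gene_id] = bool(masks[g.chrom][lo:hi].any())
    return flags


def brute_assign(peaks, genes, max_sep=25_000):
    out = {}
    for p in peaks.itertuples():
        mid = (p.start + p.end) // 2
        best = None
        for g in genes[genes["chrom"] == p.chrom].itertuples():
            d = g.tss - mid
            key = (abs(d), g.gene_id)
            if best is None or key < best[0]:
                best = (key, g.gene_id, d)
        if best is None or abs(best[2]) > max_sep:
            out[p.name] = None
        else:
            out[p.name] = (best[1], best[2])
    return out


def random_genome(rng, n_genes=25, n_domains=12, length=100_000):
    starts = np.sort(rng.choice(length - 6000, size=n_genes, replace=False))
    lengths = rng.integers(500, 4000, size=n_genes)
    genes = pd.DataFrame({
        "gene_id": [f"g{i:03d}" for i in range(n_genes)],
        "chrom": "chr", "start": starts,
        "end": np.minimum(starts + lengths, length - 1),
        "strand": rng.choice(["+", "-"], size=n_genes),
    })
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    dstarts = np.sort(rng.integers(0, length - 8000, size=n_domains))
    domains = merge_intervals(pd.DataFrame({
        "chrom": "chr", "start": dstarts,
        "end": dstarts + rng.integers(200, 8000, size=n_domains),
    }))
    return genes, domains


# ---------------------------------------------------------------------------
# unit behaviour frozen from the rules


class TestConsolidate:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "enrichment", "qvalue"])

    def test_all_thresholds_met_is_retained(self):
        merged = self._calls([("c", 0, 100, "m", 3.0, 0.001)])
        rep = self._calls([("c", 50, 150, "r", 1.0, 0.01)])
        out = consolidate_peaks(rep, rep, merged, mode="narrow")
        assert out[["start", "end"]].values.tolist() == [[0, 100]]

    def test_failing_replicate_q_drops_peak(self):
        merged = self._calls([("c", 0, 100, "m", 3.0, 0.001)])
        good = self._calls([("c", 50, 150, "r", 1.0, 0.01)])
        bad = self._calls([("c", 50, 150, "r", 1.0, 0.2)])
        assert len(consolidate_peaks(good, bad, merged)) == 0

    def test_merge_gap_boundary_inclusive(self):
        merged = self._calls([("c", 0, 100, "a", 3.0, 0.001),
                              ("c", 300, 400, "b", 3.0, 0.001)])
        rep = self._calls([("c", 0, 400, "r", 1.0, 0.01)])
        out = consolidate_peaks(rep, rep, merged, mode="narrow")
        assert out[["start", "end"]].values.tolist() == [[0, 400]]  # gap 200 <= 250

    def test_unknown_mode_rejected(self):
        empty = self._calls([])
        with pytest.raises(ValueError, match="mode"):
            consolidate_peaks(empty, empty, empty, mode="wide")

    def test_idempotent_under_remerge(self, rng):
        starts = np.sort(rng.choice(50_000, size=30, replace=False))
        merged = self._calls([("c", s, s + rng.integers(50, 400), f"m{i}", 3.0, 1e-4)
                              for i, s in enumerate(starts)])
        rep = self._calls([("c", 0, 60_000, "r", 1.0, 0.01)])
        once = consolidate_peaks(rep, rep, merged)
        again = merge_intervals(once, gap=250)
        assert once.equals(again)


class TestStitch:
    def test_full_coverage_fuses(self):
        domains = pd.DataFrame({"chrom": "c", "start": [0, 200], "end": [100, 300]})
        gaps = pd.DataFrame({"chrom": "c", "start": [100], "end": [200]})
        out = stitch_domains(domains, gaps)
        assert out[["start", "end"]].values.tolist() == [[0, 300]]

    def test_partial_coverage_does_not_fuse(self):
        domains = pd.DataFrame({"chrom": "c", "start": [0, 200], "end": [100, 300]})
        gaps = pd.DataFrame({"chrom": "c", "start": [120], "end": [180]})
        assert len(stitch_domains(domains, gaps)) == 2

    def test_no_gaps_is_identity(self):
        domains = pd.DataFrame({"chrom": "c", "start": [0, 200], "end": [100, 300]})
        assert stitch_domains(domains, None).equals(domains)

    def test_abutting_gap_pieces_cover_jointly(self):
        domains = pd.DataFrame({"chrom": "c", "start": [0, 200], "end": [100, 300]})
        gaps = pd.DataFrame({"chrom": "c", "start": [100, 150], "end": [150, 200]})
        out = stitch_domains(domains, gaps)
        assert out[["start", "end"]].values.tolist() == [[0, 300]]


class TestPcgTargets:
    def test_exactly_half_overlap_is_target(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [0],
                              "end": [1000], "strand": ["+"], "tss": [0]})
        domains = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [500]})
        res = classify_pcg_targets(genes, domains)
        assert res.loc[0, "overlap_fraction"] == 0.5 and bool(res.loc[0, "pcg_target"])

    def test_just_below_half_is_not(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [0],
                              "end": [1000], "strand": ["+"], "tss": [0]})
        domains = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [499]})
        assert not classify_pcg_targets(genes, domains)["pcg_target"].iloc[0]

    def test_invariant_to_splitting_domains_into_touching_pieces(self, rng):
        genes, domains = random_genome(rng)
        pieces = []
        for d in domains.itertuples():
            cut = (d.start + d.end) // 2
            if cut > d.start and cut < d.end:
                pieces.append(("chr", d.start, cut))
                pieces.append(("chr", cut, d.end))
            else:
                pieces.append(("chr", d.start, d.end))
        split = merge_intervals(pd.DataFrame(pieces, columns=["chrom", "start", "end"]))
        a = classify_pcg_targets(genes, domains)
        b = classify_pcg_targets(genes, split)
        assert a["pcg_target"].tolist() == b["pcg_target"].tolist()

    def test_zero_length_gene_rejected(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [5],
                              "end": [5], "strand": ["+"], "tss": [5]})
        with pytest.raises(ValueError, match="zero-length"):
            classify_pcg_targets(genes, pd.DataFrame(columns=["chrom", "start", "end"]))


class TestActivePeak:
    GENE = dict(gene_id="g", chrom="c", start=10_000, end=12_000)

    def _gene(self, strand):
        g = dict(self.GENE, strand=strand)
        g["tss"] = g["start"] if strand == "+" else g["end"] - 1
        return pd.DataFrame([g])

    def test_upstream_window_hit_plus_strand(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [7600], "end": [7700]})
        assert gene_has_active_peak(self._gene("+"), peaks).iloc[0]

    def test_beyond_window_no_hit(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [7300], "end": [7400]})
        assert not gene_has_active_peak(self._gene("+"), peaks).iloc[0]

    def test_minus_strand_window_is_right_of_body(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [13_000], "end": [13_100]})
        assert gene_has_active_peak(self._gene("-"), peaks).iloc[0]
        assert not gene_has_active_peak(self._gene("+"), peaks).iloc[0]


class TestAssignTss:
    def _genes(self, tsss):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(tsss))],
            "chrom": "c", "start": tsss, "end": [t + 100 for t in tsss],
            "strand": "+", "tss": tsss,
        })

    def test_nearest_tss_wins(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [9750], "end": [10250],
                              "name": ["p"]})
        res = assign_peaks_to_tss(peaks, self._genes([5000, 40_000]))
        assert res.loc[0, "gene_id"] == "g0" and res.loc[0, "distance"] == -5000

    def test_beyond_max_separation_unassigned(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2], "name": ["p"]})
        res = assign_peaks_to_tss(peaks, self._genes([30_002]))
        assert res.loc[0, "gene_id"] is None

    def test_tie_breaks_to_smaller_gene_id(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [9_999], "end": [10_001],
                              "name": ["p"]})
        genes = self._genes([9000, 11_000])  # both 1000 bp from midpoint 10,000
        res = assign_peaks_to_tss(peaks, genes)
        assert res.loc[0, "gene_id"] == "g0"

    def test_distal_flag_uses_1kb_cutoff(self):
        peaks = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 0], "end": [2000, 4000],
                              "name": ["near", "far"]})
        res = assign_peaks_to_tss(peaks, self._genes([0])).set_index("peak")
        assert not res.loc["near", "tss_distal"]   # |distance| = 1000 is proximal
        assert res.loc["far", "tss_distal"]        # 2000 > 1000


# ---------------------------------------------------------------------------
# randomized equivalence with the oracles


@pytest.mark.parametrize("instance", range(100))
def test_interval_operations_match_brute_force(instance):
    """All four interval classifiers agree with per-base / all-pairs oracles."""
    rng = np.random.default_rng(7000 + instance)
    genes, domains = random_genome(rng)

    got = classify_pcg_targets(genes, domains).set_index("gene_id")["pcg_target"]
    expect = brute_pcg(genes, domains)
    assert got.to_dict() == expect

    peaks = domains.assign(name=[f"p{i}" for i in range(len(domains))])
    got_active = gene_has_active_peak(genes, peaks)
    assert got_active.to_dict() == brute_active(genes, peaks)

    got_assign = assign_peaks_to_tss(peaks, genes).set_index("peak")
    expect_assign = brute_assign(peaks, genes)
    for name, val in expect_assign.items():
        if val is None:
            assert got_assign.loc[name, "gene_id"] is None
        else:
            assert got_assign.loc[name, "gene_id"] == val[0]
            assert got_assign.loc[name, "distance"] == val[1]


@pytest.mark.parametrize("instance", range(30))
def test_consolidation_matches_predicate_oracle(instance):
    """Retention equals a per-peak predicate + per-base merge oracle."""
    rng = np.random.default_rng(9000 + instance)
    n = 40
    starts = np.sort(rng.choice(80_000, size=n, replace=False))

    def calls(passing_rate, enr_hi, q_scale):
        rows = []
        for i, s in enumerate(starts):
            if rng.random() > passing_rate:
                continue
            rows.append(("c", s, s + int(rng.integers(50, 300)), f"p{i}",
                         float(rng.uniform(0, enr_hi)), float(rng.uniform(0, q_scale))))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "enrichment", "qvalue"])

    rep1, rep2 = calls(0.8, 4, 0.1), calls(0.8, 4, 0.1)
    merged = calls(1.0, 5, 0.05)
    got = consolidate_peaks(rep1, rep2, merged, mode="narrow")

    def passes(df, row, enr, q):
        sub = df[(df["enrichment"] > enr) & (df["qvalue"] < q)]
        return bool(((sub["start"] < row.end) & (sub["end"] > row.start)).any())

    kept = [r for r in merged.itertuples()
            if r.enrichment > 2 and r.qvalue < 0.01
            and passes(rep1, r, 0, 0.05) and passes(rep2, r, 0, 0.05)]
    # per-base merge oracle with gap 250: paint kept intervals dilated by the gap
    mask = np.zeros(100_000, dtype=bool)
    for r in kept:
        mask[r.start:r.end + 250] = True
    expected_blocks = 0
    prev = False
    for v in mask:
        if v and not prev:
            expected_blocks += 1
        prev = v
    assert len(got) == expected_blocks
    for r in kept:  # every kept peak is covered by the output
        assert ((got["start"] <= r.start) & (got["end"] >= r.end)).any()
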