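import itertools

import numpy as np
import pandas as pd
import pytest

from epireversion.motifs import (GRANULARITY, PWM, count_hits_in_sequence,
                                 count_motif_hits, fit_motif_effect_model,
                                 lambda_grid, motif_dose_response,
                                 pwm_threshold)
from epireversion.simulate import (_consensus_pwm, simulate_motif_regression)

BG = np.array([0.29, 0.21, 0.21, 0.29])


def enumeration_threshold(pwm: PWM, p_cutoff: float) -> float:
    """Exhaustive 4^L oracle on the same discretized score space."""
    L = len(pwm)
    scores, probs = [], []
    for seq in itertools.product(range(4), repeat=L):
        scores.append(sum(int(pwm.scores_int[i, b]) for i, b in enumerate(seq)))
        probs.append(float(np.prod([pwm.background[b] for b in seq])))
    scores = np.array(scores)
    probs = np.array(probs)
    for s in np.unique(scores):
        if probs[scores >= s].sum() <= p_cutoff + 1e-15:
            return float(s * GRANULARITY)
    return float((scores.max() + 1) * GRANULARITY)


def naive_count(seq: str, pwm: PWM, threshold: float) -> int:
    """Per-position rescanning oracle with the same dedup rules."""
    thr = int(round(threshold / GRANULARITY))
    enc = [{"A": 0, "C": 1, "G": 2, "T": 3}.get(ch, -1) for ch in seq.upper()]
    L = len(pwm)

    def strand_hits(score_matrix):
        hits = []
        for i in range(len(enc) - L + 1):
            window = enc[i:i + L]
            if any(b < 0 for b in window):
                continue
            s = sum(int(score_matrix[k, b]) for k, b in enumerate(window))
            if s >= thr:
                hits.append((i, s))
        # greedy left-to-right: best score within each overlapping chain
        kept, best, chain_end = [], None, -1
        for pos, s in hits:
            if best is not None and pos < chain_end:
                if s > best[1]:
                    best = (pos, s)
                chain_end = max(chain_end, pos + L)
            else:
                if best is not None:
                    kept.append(best[0])
                best, chain_end = (pos, s), pos + L
        if best is not None:
            kept.append(best[0])
        return kept

    fwd = strand_hits(pwm.scores_int)
    rev = strand_hits(pwm.reverse_complement().scores_int)
    return len(set(fwd) | set(rev))


class TestThreshold:
    def test_length_one_uniform_background(self):
        pwm = PWM("m", np.array([[0.97, 0.01, 0.01, 0.01]]), np.full(4, 0.25))
        thr = pwm_threshold(pwm, p_cutoff=0.25)
        assert thr == pytest.approx(pwm.scores_int.max() * GRANULARITY)

    def test_p_cutoff_one_gives_min_attainable_score(self, rng):
        pwm = PWM("m", rng.dirichlet(np.ones(4), size=4), BG)
        thr = pwm_threshold(pwm, p_cutoff=1.0)
        assert thr == pytest.approx(pwm.scores_int.min(axis=1).sum() * GRANULARITY)

    @pytest.mark.parametrize("length", [2, 3, 5, 7, 8])
    def test_dp_equals_exhaustive_enumeration(self, length):
        rng = np.random.default_rng(length)
        for rep in range(3):
            pwm = PWM(f"m{length}", rng.dirichlet(np.ones(4) * 0.7, size=length), BG)
            assert pwm_threshold(pwm, 5e-4) == pytest.approx(
                enumeration_threshold(pwm, 5e-4), abs=1e-12)

    def test_monotone_in_p_cutoff(self, rng):
        pwm = PWM("m", rng.dirichlet(np.ones(4), size=6), BG)
        cuts = [1.0, 0.1, 1e-2, 1e-3, 5e-4, 1e-5]
        thrs = [pwm_threshold(pwm, c) for c in cuts]
        assert all(a <= b + 1e-12 for a, b in zip(thrs, thrs[1:]))

    def test_invalid_cutoff_rejected(self, rng):
        pwm = PWM("m", rng.dirichlet(np.ones(4), size=3), BG)
        with pytest.raises(ValueError):
            pwm_threshold(pwm, 0.0)


class TestScanning:
    def _pwm(self, consensus="TTCCCGGAA"):
        return PWM("stat", _consensus_pwm(consensus), BG)

    def test_planted_consensus_counted_once(self, rng):
        pwm = self._pwm()
        thr = pwm_threshold(pwm)
        base = "".join(rng.choice(list("ACGT"), p=BG, size=120))
        seq = base[:40] + "TTCCCGGAA" + base[49:]
        assert count_hits_in_sequence(seq, pwm, thr) >= 1

    def test_all_n_window_counts_zero(self):
        pwm = self._pwm()
        assert count_hits_in_sequence("N" * 80, pwm, pwm_threshold(pwm)) == 0

    def test_short_sequence_warns_and_counts_zero(self):
        pwm = self._pwm()
        with pytest.warns(UserWarning, match="shorter"):
            assert count_hits_in_sequence("ACG", pwm, 0.0) == 0

    def test_palindromic_site_counts_once_across_strands(self):
        pwm = PWM("pal", _consensus_pwm("CACGTG"), BG)  # own reverse complement
        thr = pwm_threshold(pwm)
        seq = "A" * 30 + "CACGTG" + "A" * 30
        assert count_hits_in_sequence(seq, pwm, thr) == 1

    @pytest.mark.parametrize("chunk", range(4))
    def test_counts_match_naive_rescanning_oracle(self, chunk):
        rng = np.random.default_rng(100 + chunk)
        pwms = [PWM(f"m{i}", rng.dirichlet(np.ones(4) * 0.5, size=int(rng.integers(4, 9))), BG)
                for i in range(3)]
        windows = {f"w{j}": "".join(rng.choice(list("ACGT"), p=BG, size=150))
                   for j in range(25)}
        counts = count_motif_hits(windows, pwms, background=BG, p_cutoff=5e-3)
        for p in pwms:
            thr = pwm_threshold(p, 5e-3)
            for name, seq in windows.items():
                assert counts.loc[name, p.motif_id] == naive_count(seq, p, thr)

    def test_reverse_complementing_windows_preserves_counts(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        pwm = self._pwm()
        windows = {f"w{j}": "".join(rng.choice(list("ACGT"), p=BG, size=100))
                   for j in range(20)}
        rc_windows = {k: v.translate(comp)[::-1] for k, v in windows.items()}
        a = count_motif_hits(windows, [pwm], background=BG)
        b = count_motif_hits(rc_windows, [pwm], background=BG)
        assert a[pwm.motif_id].sum() == b[pwm.motif_id].sum()


class TestEffectModel:
    def test_lambda_grid_matches_printed_sequence(self):
        grid = lambda_grid()
        assert len(grid) == 51
        assert grid[0] == pytest.approx(100.0) and grid[-1] == pytest.approx(1e-3)

    def test_all_zero_counts_select_nothing(self):
        counts = pd.DataFrame(0, index=range(100), columns=[f"m{i}" for i in range(5)])
        res = fit_motif_effect_model(counts, np.zeros(100), np.zeros(100), seed=0)
        assert not res["selected"].any()

    def test_too_few_peaks_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="50"):
            fit_motif_effect_model(counts, np.zeros(10), np.zeros(10), seed=0)

    def test_planted_causal_motifs_recovered_with_signs(self):
        counts, yc, yt, betas = simulate_motif_regression(seed=3)
        res = fit_motif_effect_model(counts, yc, yt, seed=3).set_index("motif")
        assert bool(res.loc["Stat92E", "selected"]) and bool(res.loc["zfh1", "selected"])
        assert res.loc["Stat92E", "t_constant"] > 0
        assert res.loc["zfh1", "t_constant"] < 0

    def test_permuted_response_selects_nothing(self):
        counts, yc, yt, _ = simulate_motif_regression(seed=4)
        rng = np.random.default_rng(4)
        res = fit_motif_effect_model(counts, rng.permutation(yc),
                                     rng.permutation(yt), seed=4)
        assert res["selected"].sum() <= 1

    def test_scaling_a_count_column_preserves_selection(self):
        counts, yc, yt, _ = simulate_motif_regression(seed=6, n_peaks=400)
        res1 = fit_motif_effect_model(counts, yc, yt, seed=6).set_index("motif")
        scaled = counts.copy()
        scaled["Stat92E"] = scaled["Stat92E"] * 7
        res2 = fit_motif_effect_model(scaled, yc, yt, seed=6).set_index("motif")
        assert bool(res1.loc["Stat92E", "selected"]) == bool(res2.loc["Stat92E", "selected"])

    def test_largest_lambda_kills_all_coefficients(self):
        from sklearn.linear_model import Lasso
        counts, yc, _, _ = simulate_motif_regression(seed=7, n_peaks=300)
        X = counts.to_numpy(float)
        Z = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        model = Lasso(alpha=lambda_grid()[0], fit_intercept=True)
        model.fit(Z, yc)
        assert np.allclose(model.coef_, 0.0)


class TestDoseResponse:
    def test_planted_positive_effect_has_increasing_medians(self, rng):
        counts = rng.poisson(1.2, size=2000)
        lfc = 0.8 * counts + rng.normal(0, 0.3, size=2000)
        res = motif_dose_response(lfc, counts)
        assert res["median"].is_monotonic_increasing
        assert (res["p_vs_zero"].dropna() < 1e-5).all()

    def test_absent_motif_yields_single_bin_without_test(self, rng):
        lfc = rng.normal(size=100)
        with pytest.warns(UserWarning, match="empty"):
            res = motif_dose_response(lfc, np.zeros(100, dtype=int))
        assert len(res) == 1 and np.isnan(res.loc[0, "p_vs_zero"])

    def test_null_response_gives_large_p(self, rng):
        counts = rng.poisson(1.0, size=3000)
        lfc = rng.normal(size=3000)
        res = motif_dose_response(lfc, counts)
        assert (res["p_vs_zero"].dropna() > 0.01).all()
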