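import numpy as np
import pandas as pd
import pytest

from epireversion.som import (HexGrid, batch_update, clip_percentiles,
                              label_gene_clusters, label_units_atac,
                              label_units_genes, select_and_cluster_atac,
                              select_de_genes, train_supersom)


class TestHexGrid:
    def test_toroidal_row_wraps_to_distance_one(self):
        grid = HexGrid(5, 1, toroidal=True)
        d = grid.distances()
        assert d[0, 4] == pytest.approx(1.0)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        for toroidal in (True, False):
            d = HexGrid(3, 2, toroidal=toroidal).distances()
            np.testing.assert_allclose(d, d.T)
            np.testing.assert_allclose(np.diag(d), 0.0)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            HexGrid(1, 1)


class TestTraining:
    def test_zero_epochs_assigns_to_initial_codebooks(self, rng):
        X = rng.normal(size=(50, 3))
        model = train_supersom([X], HexGrid(2, 2), seed=3, epochs=0)
        d2 = ((X[:, None, :] - np.asarray(model.layers[0])[None]) ** 2).sum(-1)
        np.testing.assert_array_equal(model.assignment, d2.argmin(axis=1))

    def test_separated_blobs_land_on_distinct_units(self, rng):
        a = rng.normal(0, 0.1, size=(60, 2))
        b = rng.normal(8, 0.1, size=(60, 2))
        X = np.vstack([a, b])
        model = train_supersom([X], HexGrid(2, 1, toroidal=False), seed=0)
        ua = set(model.assignment[:60])
        ub = set(model.assignment[60:])
        assert len(ua) == 1 and len(ub) == 1 and ua != ub  # 100% purity

    def test_batch_update_invariant_to_row_duplication(self, rng):
        X = rng.normal(size=(30, 2))
        code = [rng.normal(size=(4, 2))]
        bmu = rng.integers(0, 4, size=30)
        H = np.exp(-HexGrid(2, 2).distances())
        once = batch_update([X], code, bmu, H)
        dup = batch_update([np.vstack([X, X])], code, np.concatenate([bmu, bmu]), H)
        np.testing.assert_allclose(once[0], dup[0])

    def test_training_reduces_quantization_error(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 3))
            init = train_supersom([X], HexGrid(3, 2), seed=seed, epochs=0)
            trained = train_supersom([X], HexGrid(3, 2), seed=seed, epochs=100)
            assert trained.quantization_error <= init.quantization_error + 1e-12

    def test_assignment_invariant_to_row_order(self, rng):
        X = rng.normal(size=(80, 3))
        perm = rng.permutation(80)
        m1 = train_supersom([X], HexGrid(3, 2), seed=5)
        m2 = train_supersom([X[perm]], HexGrid(3, 2), seed=5)
        np.testing.assert_array_equal(m1.assignment[perm], m2.assignment)

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            train_supersom([X], HexGrid(2, 1))

    def test_mismatched_layer_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="rows"):
            train_supersom([rng.normal(size=(10, 2)), rng.normal(size=(9, 1))],
                           HexGrid(2, 1))


class TestSelection:
    def _res(self, ids, padj, lfc):
        return pd.DataFrame({"feature_id": ids, "baseMean": 50.0,
                             "log2FoldChange": lfc, "pvalue": padj, "padj": padj})

    def test_selection_rules(self):
        ids = ["kept", "small_lfc", "control_sig"]
        constant = self._res(ids, [0.04, 0.04, 0.9], [1.2, 0.8, 0.1])
        transient = self._res(ids, [0.9, 0.9, 0.9], [0.0, 0.0, 0.0])
        control = self._res(ids, [0.9, 0.9, 0.01], [0.0, 0.0, 2.0])
        lfc = select_de_genes({"constant": constant, "transient_d9": transient},
                              control)
        assert list(lfc.index) == ["kept"]

    def test_mismatched_ids_rejected(self):
        a = self._res(["g1"], [0.5], [0.0])
        b = self._res(["g2"], [0.5], [0.0])
        with pytest.raises(ValueError, match="feature ids"):
            select_de_genes({"constant": a}, b)

    def test_missing_padj_treated_as_not_significant(self):
        const = self._res(["g1"], [np.nan], [3.0])
        ctrl = self._res(["g1"], [np.nan], [0.0])
        assert len(select_de_genes({"constant": const}, ctrl)) == 0


class TestClip:
    def test_no_value_escapes_own_percentiles(self, rng):
        m = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        clipped = clip_percentiles(m)
        for col in m:
            lo, hi = np.percentile(m[col], [5, 95])
            assert clipped[col].min() >= lo - 1e-12
            assert clipped[col].max() <= hi + 1e-12

    def test_all_equal_column_unchanged(self):
        m = pd.DataFrame({"a": [2.0] * 10})
        assert clip_percentiles(m)["a"].tolist() == [2.0] * 10

    def test_ten_percent_mass_clipped_on_uniform(self, rng):
        vals = rng.uniform(size=100)
        m = pd.DataFrame({"a": vals})
        clipped = clip_percentiles(m)
        changed = (clipped["a"] != m["a"]).sum()
        assert changed == 10  # 5 below P5 + 5 above P95 under linear interpolation

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            clip_percentiles(pd.DataFrame({"a": []}))


class TestLabelling:
    def test_sign_patterns(self):
        labels = label_units_genes(np.array([2.0, 2.0, 0.1, -2.0]),
                                   np.array([1.8, 0.1, 1.5, -1.9]))
        assert labels[:3] == ["irreversible", "reversible", "transient-specific"]
        assert labels[3] == "down1"

    def test_down_ordering_by_constant_mean(self):
        labels = label_units_genes(np.array([-1.0, -3.0, 0.0]),
                                   np.array([-1.0, -3.0, -2.0]))
        # most negative constant mean gets down1
        assert labels[1] == "down1" and labels[0] == "down2" and labels[2] == "down3"

    def test_ambiguous_unit_warns_and_uses_nearest_rule(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            labels = label_units_genes(np.array([2.0]), np.array([-2.0]))
        assert len(labels) == 1

    def test_atac_sign_rule(self):
        labels = label_units_atac(np.array([1.5, 2.0, -2.0]),
                                  np.array([1.8, 0.1, -1.8]))
        assert labels == ["irreversible", "reversible", "decreased"]


class TestAtacSelection:
    def _res(self, ids, padj, lfc, base):
        return pd.DataFrame({"feature_id": ids, "baseMean": base,
                             "log2FoldChange": lfc, "pvalue": padj, "padj": padj})

    def test_basemean_floor_excludes(self, rng):
        n = 60
        ids = [f"p{i}" for i in range(n)]
        lfc = np.where(np.arange(n) % 3 == 0, 2.0, np.where(np.arange(n) % 3 == 1, -2.0, 1.5))
        padj = np.full(n, 1e-4)
        base = np.full(n, 100.0)
        base[0] = 10.0  # log10 = 1.0 < 1.25 -> excluded
        rc = self._res(ids, padj, lfc, base)
        rt = self._res(ids, padj, lfc * 0.9, base)
        classes, model = select_and_cluster_atac(rc, rt, seed=0)
        assert "p0" not in set(classes["peak"])
        assert len(classes) == n - 1

    def test_planted_patterns_get_expected_labels(self, rng):
        n = 90
        ids = [f"p{i}" for i in range(n)]
        kind = np.arange(n) % 3
        lfc_c = np.select([kind == 0, kind == 1, kind == 2], [2.0, 2.2, -2.0])
        lfc_t = np.select([kind == 0, kind == 1, kind == 2], [1.8, 0.0, -1.8])
        noise = rng.normal(0, 0.1, size=n)
        rc = self._res(ids, np.full(n, 1e-4), lfc_c + noise, 100.0)
        rt = self._res(ids, np.full(n, 1e-4), lfc_t + noise, 100.0)
        classes, _ = select_and_cluster_atac(rc, rt, seed=1)
        got = classes.set_index("peak")["cluster"]
        assert (got[[f"p{i}" for i in range(0, n, 3)]] == "irreversible").mean() > 0.9
        assert (got[[f"p{i}" for i in range(1, n, 3)]] == "reversible").mean() > 0.9
        assert (got[[f"p{i}" for i in range(2, n, 3)]] == "decreased").mean() > 0.9


def test_planted_class_recovery_through_full_path():
    """Selection -> clip -> SOM -> labels recovers planted gene classes."""
    from epireversion.differential import Contrast, nb_wald_test
    from epireversion.simulate import (SimulationConfig, SyntheticTruth,
                                       simulate_counts)

    cfg = SimulationConfig(seed=77, n_genes=1200, n_peaks=10)
    counts, _, design, truth = simulate_counts(cfg, SyntheticTruth())
    results = {c: nb_wald_test(counts, design, Contrast(f"{c}_ph", f"{c}_w"))
               for c in cfg.conditions}
    lfc = select_de_genes({c: results[c] for c in
                           ("constant", "transient_d9", "transient_d11")},
                          results["no_kd"])
    clipped = clip_percentiles(lfc)
    model = train_supersom(
        [clipped[["constant"]].to_numpy(),
         clipped[["transient_d9", "transient_d11"]].to_numpy()],
        HexGrid(3, 2, toroidal=True), seed=1)
    labels = label_gene_clusters(model, clipped).set_index("feature_id")["cluster"]
    truth_cls = pd.Series(truth.gene_class).replace(
        {"transient_specific": "transient-specific"})
    for lab in ("irreversible", "reversible"):
        planted = truth_cls[truth_cls == lab].index
        assert (labels.reindex(planted) == lab).mean() >= 0.9
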