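import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from organoidbench import reference
from organoidbench.io import CellCounts, GeneSet
from organoidbench.simulate import SimulationConfig, build_truth, simulate_sc_counts


@pytest.fixture(scope="module")
def two_type_cells():
    cfg = SimulationConfig(
        n_genes=400,
        n_markers_per_type=15,
        cell_types=("Stem", "Enterocyte"),
        sc_cells_per_type=50,
        seed=42,
    )
    truth = build_truth(cfg)
    cells, labels = simulate_sc_counts(truth, cfg)
    return cfg, truth, cells, np.asarray(labels)


class TestNormalizeCells:
    def test_totals_scaled_to_median(self):
        counts = np.zeros((2, 3), dtype=np.int64)
        counts[0] = [50, 30, 20]  # total 100
        counts[1] = [150, 90, 60]  # total 300
        cells = CellCounts(["c1", "c2"], ["g1", "g2", "g3"], counts)
        norm = reference.normalize_cells(cells)
        assert norm.linear.sum(axis=1).to_numpy() == pytest.approx([200.0, 200.0])

    def test_single_cell_unchanged(self):
        cells = CellCounts(["c1"], ["g1", "g2"], np.array([[3, 7]]))
        norm = reference.normalize_cells(cells)
        assert norm.linear.sum(axis=1).to_numpy() == pytest.approx([10.0])

    def test_unexpressed_gene_removed(self):
        cells = CellCounts(["c1", "c2"], ["g1", "dead"], np.array([[3, 0], [5, 0]]))
        norm = reference.normalize_cells(cells)
        assert list(norm.linear.columns) == ["g1"]

    def test_zero_total_cell_dropped_with_warning(self):
        cells = CellCounts(["c1", "empty"], ["g1", "g2"], np.array([[3, 1], [0, 0]]))
        with pytest.warns(UserWarning, match="zero-total"):
            norm = reference.normalize_cells(cells)
        assert norm.cell_ids == ["c1"] and norm.n_dropped == 1

    def test_log_is_log10_of_linear_plus_one(self, two_type_cells):
        _, _, cells, _ = two_type_cells
        norm = reference.normalize_cells(cells)
        assert norm.log.to_numpy() == pytest.approx(np.log10(norm.linear.to_numpy() + 1))


class TestClusterCells:
    def test_two_separated_types_perfect_ari(self, two_type_cells):
        _, _, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        pred = reference.cluster_cells(norm, k=2, seed=0)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_k_equals_cells_gives_singletons(self):
        rng = np.random.default_rng(1)
        cells = CellCounts(
            [f"c{i}" for i in range(6)],
            [f"g{i}" for i in range(20)],
            rng.poisson(20, size=(6, 20)),
        )
        norm = reference.normalize_cells(cells)
        pred = reference.cluster_cells(norm, k=6, seed=0)
        assert len(np.unique(pred)) == 6

    def test_k_above_cells_rejected(self, two_type_cells):
        _, _, cells, _ = two_type_cells
        norm = reference.normalize_cells(cells)
        with pytest.raises(ValueError, match="exceeds"):
            reference.cluster_cells(norm, k=101, seed=0)

    def test_deterministic_given_seed(self, two_type_cells):
        _, _, cells, _ = two_type_cells
        norm = reference.normalize_cells(cells)
        a = reference.cluster_cells(norm, k=2, seed=9)
        b = reference.cluster_cells(norm, k=2, seed=9)
        assert (a == b).all()

    def test_recluster_splits_target_only(self, two_type_cells):
        _, _, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        pred = reference.cluster_cells(norm, k=1, seed=0)
        split = reference.recluster(norm, pred, target=0, k=2, seed=0)
        assert len(np.unique(split)) == 2
        assert adjusted_rand_score(labels, split) == 1.0


class TestAssignTypes:
    def test_planted_simulation_fully_typed(self, two_type_cells):
        _, truth, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        pred = reference.cluster_cells(norm, k=2, seed=0)
        sets = [GeneSet(t, tuple(g)) for t, g in truth.marker_genes.items()]
        table = reference.assign_cell_types(pred, sets, norm)
        assert (table["status"] == "ok").all()
        # the cluster holding Stem-labelled cells must be typed Stem
        for cluster in np.unique(pred):
            majority = pd.Series(labels[pred == cluster]).mode()[0]
            assert table.loc[cluster, "cell_type"] == majority

    def test_swapping_type_names_swaps_assignments(self, two_type_cells):
        _, truth, cells, _ = two_type_cells
        norm = reference.normalize_cells(cells)
        pred = reference.cluster_cells(norm, k=2, seed=0)
        types = list(truth.marker_genes)
        sets = [GeneSet(t, tuple(truth.marker_genes[t])) for t in types]
        swapped = [
            GeneSet(types[1], tuple(truth.marker_genes[types[0]])),
            GeneSet(types[0], tuple(truth.marker_genes[types[1]])),
        ]
        a = reference.assign_cell_types(pred, sets, norm)["cell_type"]
        b = reference.assign_cell_types(pred, swapped, norm)["cell_type"]
        assert set(zip(a, b)) == {(types[0], types[1]), (types[1], types[0])}

    def test_cluster_without_marker_expression_unassigned(self):
        counts = np.array([[10, 0], [12, 0], [9, 0]])
        cells = CellCounts(["c1", "c2", "c3"], ["expressed", "markerless"], counts)
        norm = reference.normalize_cells(cells)  # removes the all-zero gene
        table = reference.assign_cell_types(
            np.zeros(3, dtype=int), [GeneSet("T", ("markerless",))], norm
        )
        assert table.loc[0, "status"] == "unassigned"


class TestDefineMarkers:
    def test_planted_markers_selected(self, two_type_cells):
        _, truth, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        table = reference.define_markers(norm, labels, "Stem")
        found = set(table.index[table["selected"]])
        planted = set(truth.marker_genes["Stem"])
        assert len(found & planted) / len(planted) >= 0.9

    def test_low_fold_change_excluded_regardless_of_p(self):
        rng = np.random.default_rng(7)
        n = 60
        base = rng.poisson(100, size=(n, 30))
        base[:30, 0] = rng.poisson(200, 30)  # 2-fold: log2FC = 1 < 2
        cells = CellCounts(
            [f"c{i}" for i in range(n)], [f"g{i}" for i in range(30)], base
        )
        norm = reference.normalize_cells(cells)
        labels = np.array([0] * 30 + [1] * 30)
        table = reference.define_markers(norm, labels, 0)
        assert not table.loc["g0", "selected"]
        assert table.loc["g0", "log2FoldChange"] < 2

    def test_high_fold_change_with_noisy_groups_needs_significance(self):
        # strong mean separation but tiny groups and huge spread: adjusted p
        # stays above the threshold so the gene is excluded
        rng = np.random.default_rng(11)
        n = 8
        counts = rng.poisson(50, size=(n, 40))
        counts[:4, 0] = [1, 2, 2000, 4000]
        counts[4:, 0] = [1, 1, 2, 2]
        cells = CellCounts(
            [f"c{i}" for i in range(n)], [f"g{i}" for i in range(40)], counts
        )
        norm = reference.normalize_cells(cells)
        labels = np.array([0] * 4 + [1] * 4)
        table = reference.define_markers(norm, labels, 0)
        row = table.loc["g0"]
        assert row["log2FoldChange"] >= 2
        assert row["padj"] >= 0.05
        assert not row["selected"]

    def test_small_cluster_rejected(self, two_type_cells):
        _, _, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        bad = labels.copy()
        bad[:2] = "tiny"
        bad[2:] = "rest"
        with pytest.raises(ValueError, match="fewer than 3"):
            reference.define_markers(norm, bad, "tiny")


class TestBuildSignature:
    def test_single_type_signature_is_mean_profile(self, two_type_cells):
        _, truth, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        markers = {"Stem": list(truth.marker_genes["Stem"])}
        stem_only = labels.copy()
        sig = reference.build_signature(norm, stem_only, markers, type_order=("Stem",))
        expected = norm.linear.loc[labels == "Stem", markers["Stem"]].mean(axis=0)
        assert sig.profiles["Stem"].to_numpy() == pytest.approx(expected.to_numpy())

    def test_missing_marker_named_in_error(self, two_type_cells):
        _, truth, cells, labels = two_type_cells
        norm = reference.normalize_cells(cells)
        with pytest.raises(ValueError, match="ghost_gene"):
            reference.build_signature(norm, labels, {"Stem": ["ghost_gene"]})

    def test_planted_signature_well_conditioned(self, planted_signature):
        assert np.linalg.cond(planted_signature.profiles.to_numpy()) < 50

    def test_duplicate_marker_rows_rejected(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g1"], columns=["A", "B"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            reference.SignatureMatrix(profiles, {"A": ["g1"], "B": ["g1"]})


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_markers_and_types(self, default_study, normalized_cells):
        cfg, _, truth, _, cells, labels = default_study
        norm = normalized_cells
        pred = reference.cluster_cells(norm, k=len(cfg.cell_types), seed=cfg.seed)
        sets = [GeneSet(t, tuple(g)) for t, g in truth.marker_genes.items()]
        table = reference.assign_cell_types(pred, sets, norm)
        assert (table["status"] == "ok").all()
        assigned = set(table["cell_type"])
        assert assigned == set(cfg.cell_types)  # all types found, no false types
        for cluster, ctype in table["cell_type"].items():
            markers = reference.define_markers(norm, pred, cluster)
            found = set(markers.index[markers["selected"]])
            planted = set(truth.marker_genes[ctype])
            assert len(found & planted) / len(planted) >= 0.9
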