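"""Hex-grid SOM training, node grouping, cell-type assignment and
per-cluster statistics."""

import numpy as np
import pandas as pd
import pytest

from splicemark.som import (
    ClusterAssignment,
    SOMConfig,
    SOMModel,
    assign_celltypes,
    best_matching_unit,
    build_gene_matrix,
    cluster_se_stats,
    grid_distances,
    group_nodes,
    hex_grid_coords,
    map_rows,
    quantization_error,
    train_som,
)


def _model_from_codebook(codebook, nx, ny):
    grid = hex_grid_coords(nx, ny)
    return SOMModel(
        config=SOMConfig(nx=nx, ny=ny),
        codebook=np.asarray(codebook, dtype=float),
        grid_xy=grid,
        seed=0,
        quantization_error_init=0.0,
        quantization_error_final=0.0,
    )


class TestGrid:
    def test_hex_neighbors_unit_distance(self):
        d = grid_distances(hex_grid_coords(4, 4))
        # node 0 = (0,0); node 1 = (1,0); node 4 = row 1 col 0 at (0.5, sqrt3/2)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 4] == pytest.approx(1.0)
        assert d[0, 0] == 0.0

    def test_grid_size(self):
        assert hex_grid_coords(12, 8).shape == (96, 2)


class TestBMU:
    def test_matches_brute_force_on_3x3_grid(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            codebook = rng.normal(size=(9, 5))
            x = rng.normal(size=5)
            dists = [float(((w - x) ** 2).sum()) for w in codebook]
            brute = min(range(9), key=lambda i: (dists[i], i))
            assert best_matching_unit(codebook, x) == brute

    def test_tie_breaks_to_lowest_index(self):
        codebook = np.zeros((9, 3))
        assert best_matching_unit(codebook, np.ones(3)) == 0


class TestTraining:
    def test_single_input_converges_to_fixed_point(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]])
        model = train_som(m, SOMConfig(nx=3, ny=3, epochs=20, row_scaling="none"), seed=0)
        assert np.abs(model.codebook - np.array([1.0, 2.0, 3.0])).max() < 1e-6

    def test_quantization_error_never_worse_than_init(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (30, 6)), rng.normal(5, 1, (30, 6))])
        model = train_som(pd.DataFrame(X), SOMConfig(nx=5, ny=4, epochs=30), seed=3)
        assert model.quantization_error_final <= model.quantization_error_init

    def test_same_seed_identical_codebooks(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(20, 4)))
        cfg = SOMConfig(nx=4, ny=3, epochs=15)
        a = train_som(m, cfg, seed=9)
        b = train_som(m, cfg, seed=9)
        assert np.array_equal(a.codebook, b.codebook)
        c = train_som(m, cfg, seed=10)
        assert not np.array_equal(a.codebook, c.codebook)

    def test_non_finite_input_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            train_som(m, SOMConfig(nx=2, ny=2, epochs=2))


class TestGrouping:
    def test_two_blobs_split_perfectly(self):
        rng = np.random.default_rng(6)
        codebook = np.vstack(
            [rng.normal(0, 0.05, (6, 4)), rng.normal(9, 0.05, (6, 4))]
        )
        model = _model_from_codebook(codebook, nx=4, ny=3)
        labels, curve = group_nodes(model, k=2)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
        assert set(curve["k"]) == set(range(2, 13))

    def test_singleton_clusters_maximal_homogeneity(self):
        rng = np.random.default_rng(7)
        model = _model_from_codebook(rng.normal(size=(6, 3)), nx=3, ny=2)
        labels, curve = group_nodes(model, k=6, k_range=(2, 6))
        assert len(set(labels)) == 6
        assert curve.loc[curve["k"] == 6, "homogeneity"].item() == pytest.approx(1.0)

    def test_k_exceeding_nodes_rejected(self):
        model = _model_from_codebook(np.zeros((6, 3)), nx=3, ny=2)
        with pytest.raises(ValueError, match="exceeds"):
            group_nodes(model, k=7)


class TestAssignment:
    def _planted(self):
        rng = np.random.default_rng(11)
        # genes 0..9 hot in ct a/b, genes 10..19 hot in ct c/d
        block = np.ones((10, 4)) * 0.5
        top = block.copy()
        top[:, :2] = 5.0
        bottom = block.copy()
        bottom[:, 2:] = 5.0
        X = np.vstack([top, bottom]) + rng.normal(0, 0.01, (20, 4))
        return pd.DataFrame(X, index=[f"g{i:02d}" for i in range(20)], columns=list("abcd"))

    def test_planted_structure_assigns_celltypes_consistently(self):
        m = self._planted()
        model = train_som(m, SOMConfig(nx=4, ny=3, epochs=40), seed=2)
        labels, _ = group_nodes(model, k=2)
        assignment = assign_celltypes(m, model, labels)
        cc = assignment.celltype_cluster
        assert cc["a"] == cc["b"] and cc["c"] == cc["d"] and cc["a"] != cc["c"]

    def test_column_permutation_permutes_assignment(self):
        m = self._planted()
        model = train_som(m, SOMConfig(nx=4, ny=3, epochs=40), seed=2)
        labels, _ = group_nodes(model, k=2)
        a = assign_celltypes(m, model, labels).celltype_cluster
        b = assign_celltypes(m[list("dcba")], model, labels).celltype_cluster
        assert a == b  # same mapping per cell type regardless of column order

    def test_gene_matrix_from_records(self):
        rec = pd.DataFrame(
            {
                "type": ["SE"] * 4 + ["RI"],
                "gene_id": ["g2", "g2", "g1", "g1", "g3"],
                "celltype": ["a", "b", "a", "b", "a"],
                "enrichment_per_kb": [1.0, 2.0, 3.0, 4.0, 9.0],
            }
        )
        m = build_gene_matrix(rec, etype="SE")
        assert list(m.index) == ["g1", "g2"]  # lexicographic; RI gene excluded
        assert m.loc["g2", "b"] == 2.0

    def test_missing_entries_are_zero(self):
        rec = pd.DataFrame(
            {
                "type": ["SE", "SE"],
                "gene_id": ["g1", "g2"],
                "celltype": ["a", "b"],
                "enrichment_per_kb": [1.0, 2.0],
            }
        )
        m = build_gene_matrix(rec)
        assert m.loc["g1", "b"] == 0.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            build_gene_matrix(
                pd.DataFrame({"type": [], "gene_id": [], "celltype": [], "enrichment_per_kb": []})
            )


class TestClusterStats:
    def test_identical_groups_null(self):
        vals = np.arange(1.0, 41.0)
        cs = cluster_se_stats(1, vals, vals.copy(), n_perm=500, seed=0)
        assert cs.log2_fold_change == 0.0
        assert cs.p_value > 0.9

    def test_exact_doubling_gives_log2fc_one(self):
        non = np.array([1.0, 2.0, 3.0, 4.0])
        cs = cluster_se_stats(1, 2 * non, non, n_perm=200, seed=0, eps=1e-15)
        assert cs.log2_fold_change == pytest.approx(1.0, abs=1e-9)

    def test_zero_exceedances_reported_below_resolution(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 0.1, 200)
        b = rng.normal(0, 0.1, 200)
        cs = cluster_se_stats(1, a, b, n_perm=1000, seed=1)
        assert cs.p_value <= 1.0 / 1000
        assert cs.p_label.startswith("<")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cluster_se_stats(1, [], [1.0])
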