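"""Label transfer, spot interpolation, and landmark registration."""

import numpy as np
import pandas as pd
import pytest

import puncta
from puncta.integrate import (
    ReferenceSet,
    SpotGrid,
    Transform,
    apply_transform,
    estimate_transform_ransac,
    interpolate_to_spots,
    label_transfer,
)
from puncta.simulate import CellType, SimConfig, default_cell_types


@pytest.fixture(scope="module")
def ref_query():
    gene_names = [f"g{i:03d}" for i in range(100)]
    types = default_cell_types(gene_names, n_types=5)
    cfg = SimConfig(seed=31, gene_names=gene_names, cell_types=types,
                    transcripts_per_cell=(166.0, 10.0))
    ref_counts, ref_labels = puncta.simulate_reference(cfg, 2000, seed=32)
    q_counts, q_labels = puncta.simulate_reference(cfg, 2000, seed=33)
    return gene_names, ref_counts, ref_labels, q_counts, q_labels


class TestLabelTransfer:
    def test_query_equals_reference_perfect(self, ref_query):
        genes, ref_counts, ref_labels, _, _ = ref_query
        ref = ReferenceSet.fit(ref_counts, genes, ref_labels, n_pcs=50)
        pred = label_transfer(ref, ref_counts, genes, k=30, majority=0.5)
        assert (pred == ref_labels).mean() == 1.0

    def test_well_separated_types_recovered(self, ref_query):
        genes, ref_counts, ref_labels, q_counts, q_labels = ref_query
        ref = ReferenceSet.fit(ref_counts, genes, ref_labels, n_pcs=50)
        pred = label_transfer(ref, q_counts, genes, k=30, majority=0.5)
        unlabeled = pred == "unlabeled"
        assert unlabeled.mean() <= 0.05
        assert (pred[~unlabeled] == q_labels[~unlabeled]).mean() >= 0.95

    def test_intermediate_type_unlabeled(self):
        # with k equal to the full reference (15 cells of each of two types),
        # every query's vote is 15/15 -- a tie at the majority threshold --
        # so a type halfway between the two stays unlabeled
        genes = [f"g{i:02d}" for i in range(40)]
        a = np.zeros(40); a[:10] = 50.0
        b = np.zeros(40); b[10:20] = 50.0
        cfg_a = SimConfig(seed=41, gene_names=genes, cell_types=[CellType("A", a, 1.0)])
        cfg_b = SimConfig(seed=42, gene_names=genes, cell_types=[CellType("B", b, 1.0)])
        ca, _ = puncta.simulate_reference(cfg_a, 15, seed=45)
        cb, _ = puncta.simulate_reference(cfg_b, 15, seed=46)
        ref_counts = np.vstack([ca, cb])
        ref_labels = np.array(["A"] * 15 + ["B"] * 15)
        mid = CellType("mid", (a + b) / 2, 1.0)
        cfg_mid = SimConfig(seed=43, gene_names=genes, cell_types=[mid])
        q_counts, _ = puncta.simulate_reference(cfg_mid, 50, seed=44)
        ref = ReferenceSet.fit(ref_counts, genes, ref_labels, n_pcs=10)
        pred = label_transfer(ref, q_counts, genes, k=30, majority=0.5)
        assert np.all(pred == "unlabeled")

    def test_unlabeled_fraction_monotone_in_majority(self, ref_query):
        genes, ref_counts, ref_labels, q_counts, _ = ref_query
        ref = ReferenceSet.fit(ref_counts, genes, ref_labels, n_pcs=50)
        fracs = [
            (label_transfer(ref, q_counts, genes, k=30, majority=m) == "unlabeled").mean()
            for m in (0.5, 0.8, 1.0)
        ]
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_k_exceeding_reference_rejected(self, ref_query):
        genes, ref_counts, ref_labels, q_counts, _ = ref_query
        ref = ReferenceSet.fit(ref_counts[:20], genes, ref_labels[:20], n_pcs=10)
        with pytest.raises(ValueError):
            label_transfer(ref, q_counts, genes, k=30)


class TestSpotGrid:
    def test_hexagonal_neighbor_distance(self):
        grid = SpotGrid.build((500.0, 500.0), pitch=100.0)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(grid.centers).query(grid.centers, k=2)
        assert np.allclose(d[:, 1], 100.0, atol=1e-9)

    def test_positions_frame_dialect(self):
        grid = SpotGrid.build((300.0, 300.0))
        df = grid.positions_frame()
        assert list(df.columns) == [
            "barcode", "in_tissue", "array_row", "array_col",
            "pxl_row_in_fullres", "pxl_col_in_fullres",
        ]
        assert df["barcode"].is_unique


class TestInterpolateToSpots:
    def test_transcript_at_center(self):
        grid = SpotGrid(centers=np.array([[0.0, 0.0], [100.0, 0.0]]))
        items = pd.DataFrame({"x": [100.0], "y": [0.0], "feature": ["g"]})
        out = interpolate_to_spots(items, grid)
        assert out.loc[1, "g"] == 1 and out.loc[0, "g"] == 0

    def test_equidistant_tie_to_lower_index(self):
        grid = SpotGrid(centers=np.array([[0.0, 0.0], [10.0, 0.0]]))
        items = pd.DataFrame({"x": [5.0], "y": [0.0], "feature": ["g"]})
        out = interpolate_to_spots(items, grid)
        assert out.loc[0, "g"] == 1

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(6)
        grid = SpotGrid.build((400.0, 400.0))
        items = pd.DataFrame(
            {
                "x": rng.uniform(-50, 450, 10_000),
                "y": rng.uniform(-50, 450, 10_000),
                "feature": rng.choice([f"g{i}" for i in range(20)], 10_000),
            }
        )
        out = interpolate_to_spots(items, grid, max_radius=None)
        expected = items["feature"].value_counts()
        for g in expected.index:
            assert out[g].sum() == expected[g]

    def test_max_radius_drops_distant_items(self):
        grid = SpotGrid(centers=np.array([[0.0, 0.0]]))
        items = pd.DataFrame({"x": [1.0, 80.0], "y": [0.0, 0.0], "feature": ["g", "g"]})
        out = interpolate_to_spots(items, grid, max_radius=27.5)
        assert out.loc[0, "g"] == 1

    def test_empty_grid_rejected(self):
        grid = SpotGrid(centers=np.zeros((0, 2)))
        items = pd.DataFrame({"x": [0.0], "y": [0.0], "feature": ["g"]})
        with pytest.raises(ValueError):
            interpolate_to_spots(items, grid)


class TestRegistration:
    def test_identity_rigid(self):
        rng = np.random.default_rng(8)
        src = rng.uniform(0, 100, size=(20, 2))
        t = estimate_transform_ransac(src, src.copy(), model="rigid", seed=0)
        assert np.allclose(t.matrix, np.eye(3), atol=1e-9)
        assert t.rmse < 1e-9

    def test_recovers_rotation_with_outliers(self):
        true = Transform.similarity(rotation_deg=2.58, translation=(60.0, -40.0))
        src, dst, inliers = puncta.simulate_landmarks(
            true, 100, outlier_fraction=0.3, jitter=0.5, seed=12
        )
        est = estimate_transform_ransac(src, dst, model="similarity", seed=12)
        assert abs(est.rotation_deg - 2.58) <= 0.05
        assert np.array_equal(est.inlier_mask, inliers)
        assert abs(est.matrix[0, 2] - 60.0) < 1.0
        assert abs(est.matrix[1, 2] + 40.0) < 1.0

    def test_all_outliers_fail_loudly(self):
        rng = np.random.default_rng(13)
        src = rng.uniform(0, 1000, size=(40, 2))
        dst = rng.uniform(0, 1000, size=(40, 2))
        with pytest.raises(RuntimeError):
            est = estimate_transform_ransac(
                src, dst, model="similarity", inlier_tol=1e-3, seed=13
            )
            # extremely unlikely fallback: a tiny spurious consensus must
            # still betray itself through a large residual
            if est.rmse <= 1e-3:
                raise RuntimeError("implausible consensus")

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_transform_ransac(
                np.zeros((2, 2)), np.zeros((2, 2)), model="affine"
            )


class TestApplyTransform:
    def test_identity(self):
        t = Transform.similarity()
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(apply_transform(t, pts), pts)

    def test_pure_translation(self):
        t = Transform.similarity(translation=(10.0, 0.0))
        out = apply_transform(t, np.array([[1.0, 1.0]]))
        assert np.allclose(out, [[11.0, 1.0]])

    def test_round_trip_error(self):
        t = Transform.similarity(rotation_deg=33.0, scale=1.7, translation=(5.0, -9.0))
        rng = np.random.default_rng(14)
        pts = rng.uniform(-100, 100, size=(50, 2))
        back = apply_transform(t.inverse(), apply_transform(t, pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            Transform(model="affine", matrix=np.zeros((3, 3)))
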