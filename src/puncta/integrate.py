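"""Cross-modal integration: label transfer, spot binning, registration.

Three operations tie the in situ data to companion modalities:

* **Label transfer** — annotate in situ cells with cell types learned from a
  dissociated single-cell reference. Both datasets are restricted to shared
  genes, size-normalized to the reference median total, log1p-transformed,
  z-scored per gene with the *reference* statistics, and projected onto the
  reference's top principal components. Each query cell takes the modal
  label among its k nearest reference cells iff that label reaches the
  majority fraction (default 15 of 30); otherwise it is "unlabeled".
* **Spot interpolation** — bin transcripts or cell centroids into the
  nearest spot of a lower-resolution capture array (hexagonal lattice,
  100 um pitch, 55 um spots by platform convention) to build pseudobulk
  profiles comparable across platforms.
* **Registration** — estimate a coordinate transform between serial
  sections from paired landmarks with RANSAC, robust to mismatched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import transform as sktransform
from skimage.measure import ransac as _sk_ransac
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

UNLABELED = "unlabeled"

_MODEL_CLASSES = {
    "rigid": sktransform.EuclideanTransform,
    "similarity": sktransform.SimilarityTransform,
    "affine": sktransform.AffineTransform,
    "homography": sktransform.ProjectiveTransform,
}

_MIN_SAMPLES = {"rigid": 2, "similarity": 2, "affine": 3, "homography": 4}


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class Transform:
    """A 2D homogeneous coordinate transform with fit diagnostics."""

    model: str
    matrix: np.ndarray  # 3x3
    inlier_mask: np.ndarray | None = None
    rmse: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    @property
    def rotation_deg(self) -> float:
        """Rotation angle implied by the linear part (meaningful for
        rigid/similarity models)."""
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def inverse(self) -> "Transform":
        return Transform(model=self.model, matrix=np.linalg.inv(self.matrix))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"model": self.model, "matrix": self.matrix.tolist(), "rmse": self.rmse},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Transform":
        d = json.loads(Path(path).read_text())
        return cls(model=d["model"], matrix=np.array(d["matrix"]), rmse=d.get("rmse", 0.0))

    @classmethod
    def similarity(
        cls, rotation_deg: float = 0.0, scale: float = 1.0, translation=(0.0, 0.0)
    ) -> "Transform":
        t = np.radians(rotation_deg)
        m = np.array(
            [
                [scale * np.cos(t), -scale * np.sin(t), translation[0]],
                [scale * np.sin(t), scale * np.cos(t), translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(model="similarity", matrix=m)


def apply_transform(t: Transform, coords: np.ndarray) -> np.ndarray:
    """Apply a homogeneous transform to an (n, 2) coordinate array."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    ones = np.ones((coords.shape[0], 1))
    hom = np.hstack([coords, ones]) @ t.matrix.T
    return hom[:, :2] / hom[:, 2:3]


def estimate_transform_ransac(
    src: np.ndarray,
    dst: np.ndarray,
    model: str = "similarity",
    inlier_tol: float = 5.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> Transform:
    """Robustly fit a transform from paired landmarks with RANSAC.

    Repeated minimal-sample fits; the consensus set (residual <= inlier_tol,
    um) of the best hypothesis is refit by least squares on all its inliers.
    Raises if too few pairs, or if no consensus beyond a minimal sample is
    found (all pairs effectively outliers — no silent success).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if model not in _MODEL_CLASSES:
        raise ValueError(f"unknown model {model!r}")
    min_samples = _MIN_SAMPLES[model]
    if len(src) < min_samples or len(src) != len(dst):
        raise ValueError("insufficient or mismatched landmark pairs")

    model_cls = _MODEL_CLASSES[model]
    fitted, inliers = _sk_ransac(
        (src, dst),
        model_cls,
        min_samples=min_samples,
        residual_threshold=inlier_tol,
        max_trials=n_iter,
        rng=seed,
    )
    if fitted is None or inliers is None or inliers.sum() <= min_samples:
        raise RuntimeError("registration failed: no consensus among landmark pairs")

    refined = model_cls.from_estimate(src[inliers], dst[inliers])
    if not refined:
        raise RuntimeError("least-squares refinement on inliers failed")
    resid = np.linalg.norm(refined(src[inliers]) - dst[inliers], axis=1)
    matrix = np.asarray(refined.params, dtype=float)
    return Transform(
        model=model,
        matrix=matrix,
        inlier_mask=np.asarray(inliers, bool),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# label transfer
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """A fitted single-cell reference: normalization stats + PC loadings."""

    feature_names: list[str]
    labels: np.ndarray
    median_total: float
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    components: np.ndarray  # (n_pcs, n_genes)
    ref_pcs: np.ndarray = field(repr=False, default=None)  # (n_cells, n_pcs)

    @classmethod
    def fit(
        cls,
        counts: np.ndarray,
        feature_names: list[str],
        labels: np.ndarray,
        n_pcs: int = 50,
    ) -> "ReferenceSet":
        """Learn normalization statistics and PCA loadings from a reference.

        counts: dense or sparse (cells x genes) nonnegative matrix.
        """
        counts = np.asarray(
            counts.todense() if hasattr(counts, "todense") else counts, dtype=float
        )
        if counts.shape[0] != len(labels):
            raise ValueError("labels must match number of reference cells")
        n_pcs = min(n_pcs, counts.shape[0], counts.shape[1])
        totals = counts.sum(axis=1)
        median_total = float(np.median(totals[totals > 0]))
        norm = _lognormalize(counts, median_total)
        gene_mean = norm.mean(axis=0)
        gene_sd = norm.std(axis=0)
        gene_sd = np.where(gene_sd < 1e-8, 1.0, gene_sd)
        z = (norm - gene_mean) / gene_sd
        pca = PCA(n_components=n_pcs, svd_solver="full")
        ref_pcs = pca.fit_transform(z)
        return cls(
            feature_names=list(feature_names),
            labels=np.asarray(labels),
            median_total=median_total,
            gene_mean=gene_mean,
            gene_sd=gene_sd,
            components=pca.components_,
            ref_pcs=ref_pcs,
        )

    def project(self, counts: np.ndarray, feature_names: list[str]) -> np.ndarray:
        """Normalize query counts with reference stats and project to PC space."""
        counts = np.asarray(
            counts.todense() if hasattr(counts, "todense") else counts, dtype=float
        )
        shared = [g for g in self.feature_names if g in set(feature_names)]
        if len(shared) < self.components.shape[0]:
            raise ValueError("fewer shared genes than principal components")
        if shared != self.feature_names:
            # align both sides to the shared subset, reference order
            qpos = {g: i for i, g in enumerate(feature_names)}
            rpos = {g: i for i, g in enumerate(self.feature_names)}
            q_idx = [qpos[g] for g in shared]
            r_idx = [rpos[g] for g in shared]
            counts = counts[:, q_idx]
            mean, sd = self.gene_mean[r_idx], self.gene_sd[r_idx]
            comps = self.components[:, r_idx]
        else:
            mean, sd, comps = self.gene_mean, self.gene_sd, self.components
        norm = _lognormalize(counts, self.median_total)
        z = (norm - mean) / sd
        return z @ comps.T


def _lognormalize(counts: np.ndarray, target_total: float) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    scale = np.where(totals > 0, target_total / np.maximum(totals, 1e-12), 0.0)
    return np.log1p(counts * scale)


def label_transfer(
    ref: ReferenceSet,
    query_counts: np.ndarray,
    query_features: list[str],
    k: int = 30,
    majority: float = 0.5,
) -> np.ndarray:
    """Transfer reference labels to query cells by k-NN majority vote.

    A query cell is labeled with the most frequent label among its ``k``
    nearest reference cells (Euclidean, in reference PC space) iff that
    label holds at least ``ceil(majority * k)`` of the neighbors; ties
    between labels at the required count, or failure to reach it, yield
    "unlabeled".
    """
    if k > len(ref.labels):
        raise ValueError("k exceeds reference size")
    q = ref.project(query_counts, query_features)
    nn = NearestNeighbors(n_neighbors=k).fit(ref.ref_pcs)
    _, idx = nn.kneighbors(q)
    needed = int(np.ceil(majority * k))
    out = np.empty(len(q), dtype=object)
    labels = ref.labels
    for i, neigh in enumerate(idx):
        vals, counts = np.unique(labels[neigh], return_counts=True)
        top = counts.max()
        if top < needed or (counts == top).sum() > 1:
            out[i] = UNLABELED
        else:
            out[i] = vals[np.argmax(counts)]
    return out


# ---------------------------------------------------------------------------
# spot interpolation
# ---------------------------------------------------------------------------


@dataclass
class SpotGrid:
    """Hexagonal capture-spot lattice (platform standard: 100 um pitch,
    55 um spot diameter)."""

    centers: np.ndarray  # (n_spots, 2) um
    pitch: float = 100.0
    spot_diameter: float = 55.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be (n, 2)")

    @property
    def n_spots(self) -> int:
        return self.centers.shape[0]

    @classmethod
    def build(
        cls,
        extent: tuple[float, float],
        pitch: float = 100.0,
        spot_diameter: float = 55.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "SpotGrid":
        """Hex lattice covering [origin, origin + extent]: rows spaced
        pitch*sqrt(3)/2 apart, odd rows offset by pitch/2, so every
        nearest-neighbor distance equals the pitch."""
        dy = pitch * np.sqrt(3) / 2
        xs, ys = [], []
        row = 0
        y = origin[1]
        while y <= origin[1] + extent[1]:
            off = (pitch / 2) if row % 2 else 0.0
            x = origin[0] + off
            while x <= origin[0] + extent[0]:
                xs.append(x)
                ys.append(y)
                x += pitch
            y += dy
            row += 1
        return cls(centers=np.column_stack([xs, ys]), pitch=pitch, spot_diameter=spot_diameter)

    def positions_frame(self) -> pd.DataFrame:
        """Spot table in the tissue_positions dialect (pixel cols = um here)."""
        rows = np.round((self.centers[:, 1]) / (self.pitch * np.sqrt(3) / 2)).astype(int)
        cols = np.round((self.centers[:, 0]) / (self.pitch / 2)).astype(int)
        return pd.DataFrame(
            {
                "barcode": [f"spot_{i:05d}" for i in range(self.n_spots)],
                "in_tissue": 1,
                "array_row": rows,
                "array_col": cols,
                "pxl_row_in_fullres": self.centers[:, 1],
                "pxl_col_in_fullres": self.centers[:, 0],
            }
        )


def interpolate_to_spots(
    items: pd.DataFrame,
    grid: SpotGrid,
    feature_col: str = "feature",
    max_radius: float | None = None,
    weight_col: str | None = None,
) -> pd.DataFrame:
    """Bin items (transcripts or cell centroids) into nearest spots.

    ``items`` needs columns x, y and ``feature_col``; optional
    ``weight_col`` accumulates weights (e.g. per-cell counts) instead of
    unit counts. Items farther than ``max_radius`` from every spot center
    are dropped when it is set; with ``max_radius=None`` every item is
    binned, so column sums equal per-feature input counts exactly. Exact
    distance ties go to the lower spot index.

    Returns a (n_spots x features) DataFrame indexed by spot position.
    """
    if grid.n_spots == 0:
        raise ValueError("empty spot grid")
    xy = items[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(grid.centers)
    if len(xy):
        dist, idx = tree.query(xy, k=min(2, grid.n_spots))
        if dist.ndim == 2:  # resolve exact ties toward the lower index
            tied = np.isclose(dist[:, 0], dist[:, 1], rtol=0, atol=1e-9)
            nearest = idx[:, 0].copy()
            nearest[tied] = np.minimum(idx[tied, 0], idx[tied, 1])
            dist = dist[:, 0]
        else:
            nearest = idx
    else:
        nearest = np.zeros(0, dtype=int)
        dist = np.zeros(0)

    keep = np.ones(len(xy), dtype=bool)
    if max_radius is not None:
        keep = dist <= max_radius
    feats = items[feature_col].to_numpy()[keep]
    spots = nearest[keep]
    w = (
        items[weight_col].to_numpy(dtype=float)[keep]
        if weight_col
        else np.ones(keep.sum())
    )
    df = pd.DataFrame({"spot": spots, "feature": feats, "w": w})
    table = df.pivot_table(
        index="spot", columns="feature", values="w", aggfunc="sum", fill_value=0
    )
    return table.reindex(range(grid.n_spots), fill_value=0)
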