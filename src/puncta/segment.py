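"""Distance-capped nucleus expansion and transcript-to-cell assignment.

Nuclei (an integer label raster, e.g. from DAPI segmentation) are expanded
outward into cell territories: every background pixel within ``max_expansion``
micrometres (Euclidean distance to the nearest nucleus *pixel*, not the
centroid) is claimed by its nearest nucleus; expansion also stops where
another cell's territory begins, which the nearest-nucleus rule gives for
free (a distance-capped generalized Voronoi partition). Ties go to the
lower label id. Transcripts are then assigned by raster lookup of the pixel
containing their centroid, and a sparse cells x features count matrix is
accumulated from the assigned, quality-filtered transcripts.

Raster convention: pixel (row 0, col 0) covers the half-open square
[0, pixel_size) x [0, pixel_size) um, x rightward (columns), y downward
(rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import distance_transform_edt, find_objects

from .codebook import CATEGORY_GENE, Codebook

DEFAULT_MAX_EXPANSION = 15.0  # um


@dataclass
class NucleusLabelImage:
    """2D integer label raster of nuclei (0 = background, k >= 1 = nucleus k)."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")


@dataclass
class CellSegmentation:
    """Non-overlapping cell territories from nucleus expansion."""

    labels: np.ndarray
    pixel_size: float
    max_expansion: float

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellFeatureMatrix:
    """Sparse nonnegative integer counts, cells x features.

    Control-category features are carried as columns (flagged via
    ``feature_categories``) so QC can read them, and excluded by
    :meth:`gene_matrix` for analysis.
    """

    matrix: sp.csr_matrix
    cell_ids: np.ndarray
    feature_names: list[str]
    feature_categories: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.cell_ids), len(self.feature_names)):
            raise ValueError("matrix dims do not match cell/feature lists")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def gene_mask(self) -> np.ndarray:
        return np.array([c == CATEGORY_GENE for c in self.feature_categories])

    def gene_matrix(self) -> "CellFeatureMatrix":
        """Analysis view restricted to gene features (controls dropped)."""
        m = self.gene_mask()
        return CellFeatureMatrix(
            matrix=self.matrix[:, m],
            cell_ids=self.cell_ids,
            feature_names=[n for n, k in zip(self.feature_names, m) if k],
            feature_categories=[CATEGORY_GENE] * int(m.sum()),
        )


def expand_nuclei(
    nuclei: NucleusLabelImage, max_expansion: float = DEFAULT_MAX_EXPANSION
) -> CellSegmentation:
    """Expand each nucleus into its capped nearest-nucleus territory.

    Implemented as a per-label distance-transform sweep restricted to each
    nucleus's padded bounding box: a pixel takes the label whose mask is
    strictly nearest, so iterating labels in increasing order makes the
    lower-id-wins tie-break exact. Distances are Euclidean in micrometres
    between pixel centers.
    """
    lab = nuclei.labels
    if lab.size == 0:
        raise ValueError("empty label image")
    ps = nuclei.pixel_size
    pad = int(np.ceil(max_expansion / ps)) + 1
    h, w = lab.shape
    best_dist = np.full(lab.shape, np.inf)
    out = np.zeros(lab.shape, dtype=np.int32)

    slices = find_objects(lab)
    for k, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, h)
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, w)
        win = np.s_[r0:r1, c0:c1]
        mask = lab[win] == k
        if not mask.any():
            continue
        d = distance_transform_edt(~mask, sampling=ps)
        better = (d <= max_expansion) & (d < best_dist[win])
        bd = best_dist[win]
        ow = out[win]
        bd[better] = d[better]
        ow[better] = k
        best_dist[win] = bd
        out[win] = ow

    # nucleus pixels always keep their own label (distance 0)
    nz = lab > 0
    out[nz] = lab[nz]
    return CellSegmentation(labels=out, pixel_size=ps, max_expansion=max_expansion)


def assign_transcripts(
    decoded: pd.DataFrame, seg: CellSegmentation
) -> pd.DataFrame:
    """Fill ``cell_id`` by raster lookup of each transcript's (x, y) pixel.

    Out-of-bounds coordinates and background pixels map to cell_id 0
    (unassigned). Returns a copy; order preserved.
    """
    out = decoded.copy()
    h, w = seg.labels.shape
    col = np.floor(out["x"].to_numpy() / seg.pixel_size).astype(int)
    row = np.floor(out["y"].to_numpy() / seg.pixel_size).astype(int)
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    cid = np.zeros(len(out), dtype=np.int64)
    cid[inside] = seg.labels[row[inside], col[inside]]
    out["cell_id"] = cid
    return out


def build_cell_feature_matrix(
    assigned: pd.DataFrame,
    codebook: Codebook,
    cell_ids: np.ndarray | None = None,
) -> CellFeatureMatrix:
    """Accumulate assigned transcripts into a cells x features count matrix.

    Entry (c, f) counts transcripts of feature f with cell_id c > 0;
    unassigned transcripts (cell_id 0) are excluded. Features follow the
    codebook order, controls included as flagged columns. ``cell_ids``
    fixes the row universe (e.g. all segmented cells, so empty cells appear
    as zero rows); by default rows are the cells observed in the input.
    """
    kept = assigned[assigned["cell_id"] > 0]
    if cell_ids is None:
        cell_ids = np.unique(kept["cell_id"].to_numpy())
    cell_ids = np.asarray(cell_ids)
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    rows = kept["cell_id"].map(cell_pos).to_numpy()
    cols = kept["code_id"].to_numpy()
    if np.isnan(rows).any() if rows.dtype.kind == "f" else False:
        raise ValueError("assigned transcripts reference cells outside cell_ids")
    data = np.ones(len(kept), dtype=np.int64)
    mat = sp.coo_matrix(
        (data, (rows.astype(int), cols)),
        shape=(len(cell_ids), codebook.n_codes),
    ).tocsr()
    return CellFeatureMatrix(
        matrix=mat,
        cell_ids=cell_ids,
        feature_names=list(codebook.names),
        feature_categories=list(codebook.categories),
    )


def nearest_nucleus_oracle(
    xy: np.ndarray, nuclei: NucleusLabelImage, max_expansion: float = DEFAULT_MAX_EXPANSION
) -> np.ndarray:
    """Brute-force vector-space assignment: nearest nucleus pixel within cap.

    For each query point, computes the exact Euclidean distance to every
    nucleus pixel center and returns the label of the closest one within
    ``max_expansion`` (ties to the lower label), else 0. Quadratic; intended
    as an independent check of the raster pipeline on small instances.
    """
    lab = nuclei.labels
    ps = nuclei.pixel_size
    rr, cc = np.nonzero(lab)
    labs = lab[rr, cc]
    px = (cc + 0.5) * ps
    py = (rr + 0.5) * ps
    order = np.argsort(labs, kind="stable")  # lower label wins ties below
    px, py, labs = px[order], py[order], labs[order]
    out = np.zeros(len(xy), dtype=np.int64)
    for i, (x, y) in enumerate(np.asarray(xy, float)):
        d2 = (px - x) ** 2 + (py - y) ** 2
        j = np.argmin(d2)  # first minimum -> lowest label due to sort
        if d2[j] <= max_expansion**2:
            out[i] = labs[j]
    return out
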