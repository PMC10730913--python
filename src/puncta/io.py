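"""Readers and writers for the pipeline's on-disk formats.

The export layout follows the 10x-style convention: a transcripts table
(CSV, one row per decoded molecule with coordinates in micrometres and a
calibrated quality score), a cells table, and a MatrixMarket MEX triplet
(matrix.mtx + features.tsv + barcodes.tsv, features as matrix rows, the
features.tsv columns being id / name / type). Gzip-compressed variants are
read transparently. Reading tolerates both this package's column names and
the deposited-platform dialect (feature_name, x_location, ...).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .segment import CellFeatureMatrix

# deposited-platform -> internal column names
_TRANSCRIPT_ALIASES = {
    "feature_name": "feature",
    "x_location": "x",
    "y_location": "y",
    "z_location": "z",
}

_REQUIRED_TRANSCRIPT_COLS = ("feature", "x", "y", "z", "qv", "cell_id")


def _find(path: Path, *names: str) -> Path:
    for n in names:
        for cand in (path / n, path / f"{n}.gz"):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} found under {path}")


def write_transcripts(transcripts: pd.DataFrame, path: str | Path) -> None:
    df = transcripts.copy()
    if "transcript_id" not in df.columns:
        df.insert(0, "transcript_id", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_transcripts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)  # pandas infers gzip from the extension
    df = df.rename(columns=_TRANSCRIPT_ALIASES)
    missing = [c for c in _REQUIRED_TRANSCRIPT_COLS if c not in df.columns]
    if missing:
        raise ValueError(
            f"transcripts file {path} lacks columns {missing}; found {list(df.columns)}"
        )
    # deposited files mark unassigned molecules with -1 or 'UNASSIGNED'
    cid = df["cell_id"]
    if cid.dtype == object:
        df["cell_id"] = pd.to_numeric(cid, errors="coerce").fillna(0).astype(np.int64)
    else:
        df["cell_id"] = cid.fillna(0).astype(np.int64)
    df.loc[df["cell_id"] < 0, "cell_id"] = 0
    return df


def write_mex(m: CellFeatureMatrix, outdir: str | Path) -> None:
    """Write a features x barcodes MatrixMarket triplet (10x dialect)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(m.matrix.T), field="integer")
    feats = pd.DataFrame(
        {
            "id": m.feature_names,
            "name": m.feature_names,
            "type": [
                "Gene Expression" if c == "gene" else c for c in m.feature_categories
            ],
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series([f"cell_{c}" for c in m.cell_ids]).to_csv(
        outdir / "barcodes.tsv", header=False, index=False
    )


def read_mex(path: str | Path) -> CellFeatureMatrix:
    path = Path(path)
    mtx_path = _find(path, "matrix.mtx")
    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                mat = sio.mmread(fh)
        else:
            mat = sio.mmread(str(mtx_path))
    except Exception as exc:
        raise ValueError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat.T)  # back to cells x features

    feats = pd.read_csv(
        _find(path, "features.tsv"), sep="\t", header=None, dtype=str
    )
    barcodes = pd.read_csv(
        _find(path, "barcodes.tsv"), sep="\t", header=None, dtype=str
    )[0]
    if mat.shape != (len(barcodes), len(feats)):
        raise ValueError(
            f"matrix {mat.shape} inconsistent with {len(barcodes)} barcodes x "
            f"{len(feats)} features in {path}"
        )
    names = feats[1 if feats.shape[1] > 1 else 0].tolist()
    types = (
        feats[2].tolist() if feats.shape[1] > 2 else ["Gene Expression"] * len(feats)
    )
    categories = ["gene" if t == "Gene Expression" else t for t in types]
    cell_ids = np.array(
        [int(b.split("_")[-1]) if "_" in b else i + 1 for i, b in enumerate(barcodes)]
    )
    return CellFeatureMatrix(
        matrix=mat,
        cell_ids=cell_ids,
        feature_names=names,
        feature_categories=categories,
    )


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outputs(
    outdir: str | Path,
    transcripts: pd.DataFrame,
    matrix: CellFeatureMatrix,
    cells: pd.DataFrame | None = None,
) -> None:
    """Export the standard bundle: transcripts.csv, cell_feature_matrix/, cells.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcripts(transcripts, outdir / "transcripts.csv")
    write_mex(matrix, outdir / "cell_feature_matrix")
    if cells is not None:
        write_cells(cells, outdir / "cells.csv")


def read_10x_outputs(path: str | Path):
    """Read an exported bundle: (transcripts, CellFeatureMatrix, cells-or-None)."""
    path = Path(path)
    transcripts = read_transcripts(_find(path, "transcripts.csv"))
    matrix = read_mex(path / "cell_feature_matrix")
    cells = None
    try:
        cells = read_cells(_find(path, "cells.csv"))
    except FileNotFoundError:
        pass
    return transcripts, matrix, cells
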