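"""QC and benchmarking statistics for cell-feature matrices.

The summary statistics mirror what platform QC reports print: per-cell
transcript and gene distributions, median gene sensitivity (per-gene mean
counts per cell, then the median across genes — robust to a few very high
expressors), library complexity (how many genes carry half the counts),
negative-control call rates, binomial count downsampling for depth-matched
comparisons, and replicate concordance as r^2 of log pseudobulk counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .codebook import CATEGORY_GENE, CATEGORY_NEG_CODEWORD, CATEGORY_NEG_PROBE, Codebook
from .segment import CellFeatureMatrix


@dataclass
class QCSummary:
    total_cells: int
    total_transcripts: int
    transcripts_per_cell_p10: float
    transcripts_per_cell_p50: float
    transcripts_per_cell_p90: float
    median_genes_per_cell: float
    median_gene_sensitivity: float
    complexity_genes_half: int
    neg_control_probe_fraction: float
    neg_control_codeword_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def to_text(self) -> str:
        d = asdict(self)
        width = max(len(k) for k in d)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in d.items())


def _dense_genes(m: CellFeatureMatrix) -> np.ndarray:
    return np.asarray(m.gene_matrix().matrix.todense(), dtype=float)


def median_gene_sensitivity(m: CellFeatureMatrix) -> float:
    """Median over genes of the per-gene mean counts per cell (controls excluded)."""
    g = _dense_genes(m)
    if g.size == 0:
        raise ValueError("empty matrix")
    return float(np.median(g.mean(axis=0)))


def complexity_genes_for_fraction(m: CellFeatureMatrix, fraction: float = 0.5) -> int:
    """Smallest number of genes whose totals cover >= fraction of all counts."""
    g = _dense_genes(m)
    totals = np.sort(g.sum(axis=0))[::-1]
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("matrix has no counts")
    cum = np.cumsum(totals)
    return int(np.searchsorted(cum, fraction * grand) + 1)


def per_cell_stats(m: CellFeatureMatrix) -> dict:
    """Per-cell transcript/gene distribution summaries (linear-interpolated
    percentiles)."""
    g = _dense_genes(m)
    if g.shape[0] == 0:
        raise ValueError("no cells")
    per_cell = g.sum(axis=1)
    genes_per_cell = (g > 0).sum(axis=1)
    p10, p50, p90 = np.percentile(per_cell, [10, 50, 90])
    return {
        "transcripts_per_cell_p10": float(p10),
        "transcripts_per_cell_p50": float(p50),
        "transcripts_per_cell_p90": float(p90),
        "median_genes_per_cell": float(np.median(genes_per_cell)),
    }


def control_rates(transcripts: pd.DataFrame, q_threshold: float = 20.0) -> dict:
    """Fraction of quality-passing counts in each control category."""
    passing = transcripts[transcripts["qv"] >= q_threshold]
    total = len(passing)
    if total == 0:
        raise ValueError("no transcripts pass the quality threshold")
    out = {}
    for cat, key in (
        (CATEGORY_NEG_PROBE, "neg_control_probe_fraction"),
        (CATEGORY_NEG_CODEWORD, "neg_control_codeword_fraction"),
    ):
        out[key] = float((passing["category"] == cat).sum() / total)
    return out


def downsample_counts(
    m: CellFeatureMatrix, target_mean_per_cell: float, seed: int = 0
) -> CellFeatureMatrix:
    """Binomial thinning to a target mean total per cell.

    A single global retention probability p = target_mean * n_cells /
    grand_total is applied independently to every count, so the expected
    grand total is target_mean * n_cells and zero entries stay zero.
    """
    coo = m.matrix.tocoo()
    grand = coo.data.sum()
    current_mean = grand / m.n_cells if m.n_cells else 0.0
    if target_mean_per_cell > current_mean:
        raise ValueError("target mean exceeds current mean per cell")
    p = target_mean_per_cell * m.n_cells / grand if grand > 0 else 0.0
    rng = np.random.default_rng(seed)
    data = rng.binomial(coo.data.astype(np.int64), p)
    thinned = sp.coo_matrix((data, (coo.row, coo.col)), shape=m.matrix.shape).tocsr()
    thinned.eliminate_zeros()
    return CellFeatureMatrix(
        matrix=thinned,
        cell_ids=m.cell_ids,
        feature_names=list(m.feature_names),
        feature_categories=list(m.feature_categories),
    )


def replicate_concordance(
    m1: CellFeatureMatrix, m2: CellFeatureMatrix, log_scale: bool = True
) -> float:
    """Squared Pearson correlation of per-gene pseudobulk totals.

    Computed on log10(total + 1) by default, over the shared gene features.
    """
    f1 = {n: i for i, n in enumerate(m1.feature_names)}
    shared = [
        n
        for n, c in zip(m2.feature_names, m2.feature_categories)
        if c == CATEGORY_GENE and n in f1
    ]
    if len(shared) < 2:
        raise ValueError("need at least 2 shared gene features")
    t1 = np.asarray(m1.matrix.sum(axis=0)).ravel()[[f1[n] for n in shared]]
    f2 = {n: i for i, n in enumerate(m2.feature_names)}
    t2 = np.asarray(m2.matrix.sum(axis=0)).ravel()[[f2[n] for n in shared]]
    if log_scale:
        t1 = np.log10(t1 + 1.0)
        t2 = np.log10(t2 + 1.0)
    if t1.std() == 0 or t2.std() == 0:
        raise ValueError("zero variance in pseudobulk totals")
    r = np.corrcoef(t1, t2)[0, 1]
    return float(r**2)


def qc_summary(m: CellFeatureMatrix, transcripts: pd.DataFrame) -> QCSummary:
    """Full QC report from a matrix and its quality-filtered transcript table."""
    stats = per_cell_stats(m)
    rates = control_rates(transcripts)
    return QCSummary(
        total_cells=int(m.n_cells),
        total_transcripts=int(m.gene_matrix().matrix.sum()),
        transcripts_per_cell_p10=stats["transcripts_per_cell_p10"],
        transcripts_per_cell_p50=stats["transcripts_per_cell_p50"],
        transcripts_per_cell_p90=stats["transcripts_per_cell_p90"],
        median_genes_per_cell=stats["median_genes_per_cell"],
        median_gene_sensitivity=median_gene_sensitivity(m),
        complexity_genes_half=complexity_genes_for_fraction(m, 0.5),
        neg_control_probe_fraction=rates["neg_control_probe_fraction"],
        neg_control_codeword_fraction=rates["neg_control_codeword_fraction"],
    )
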