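"""Bin-wise Q-score calibration against negative-control codewords.

Raw decoder qualities are only as good as the noise model behind them; the
calibrated quality (qv) is anchored to data instead. Decoded transcripts are
binned by raw quality, and in each bin the rate of calls to
negative-control codewords — codebook entries with no physical probe, so
every call to one is a decoding error — estimates the false-discovery rate
among gene calls:

    per-codeword false-call rate = (n_ncc + 1) / N_ncc_codes   (pseudocount)
    FDR_hat = min(1, rate * N_gene_codes / max(1, n_gene_calls))
    qv_bin  = min(q_cap, -10 * log10(FDR_hat))

The +1 pseudocount keeps empty bins conservative; scaling by the number of
gene codewords converts a per-control-codeword rate into an expected count
of false gene calls. Pool-adjacent-violators enforces that qv is
non-decreasing in raw quality. Downstream analyses keep only transcripts
with qv >= 20 (Phred 20, a nominal 1% error rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import (
    CATEGORY_GENE,
    CATEGORY_NEG_CODEWORD,
    Codebook,
)

DEFAULT_Q_THRESHOLD = 20.0


@dataclass
class CalibrationTable:
    """Per-bin calibration: edges over raw_q plus estimated FDR and final qv."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    n_total: np.ndarray
    n_ncc: np.ndarray
    n_gene: np.ndarray
    fdr: np.ndarray
    qv: np.ndarray  # non-decreasing across bins

    def lookup(self, raw_q: np.ndarray) -> np.ndarray:
        """Map raw qualities to their bin's calibrated qv."""
        idx = np.searchsorted(self.bin_edges, raw_q, side="right") - 1
        idx = np.clip(idx, 0, len(self.qv) - 1)
        return self.qv[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "n_total": self.n_total,
                "n_ncc": self.n_ncc,
                "n_gene": self.n_gene,
                "fdr": self.fdr,
                "qv": self.qv,
            }
        )


def _pava_nondecreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators for a non-decreasing fit."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    # blocks as (value, weight) stacks merged left-to-right
    vals: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            c = counts[-2] + counts[-1]
            wt = wts[-2] + wts[-1]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [wt]
            counts = counts[:-2] + [c]
    out = np.empty_like(y)
    i = 0
    for v, c in zip(vals, counts):
        out[i : i + c] = v
        i += c
    return out


def calibrate(
    decoded: pd.DataFrame,
    codebook: Codebook,
    n_bins: int = 20,
    q_cap: float = 40.0,
    min_bin_calls: int = 50,
) -> tuple[CalibrationTable, pd.DataFrame]:
    """Calibrate raw qualities bin-wise; returns (table, decoded-with-qv).

    Equal-width bins over [0, q_cap]; bins with fewer than ``min_bin_calls``
    transcripts are merged with their left neighbor (leftmost merges right)
    before estimation. Requires at least one negative-control codeword in
    the codebook. The input frame is not modified; a copy with the ``qv``
    column filled is returned.
    """
    if decoded.empty:
        raise ValueError("no decoded transcripts to calibrate")
    n_ncc_codes = len(codebook.category_indices(CATEGORY_NEG_CODEWORD))
    n_gene_codes = len(codebook.category_indices(CATEGORY_GENE))
    if n_ncc_codes == 0:
        raise ValueError("codebook has no negative-control codewords")

    edges = np.linspace(0.0, q_cap, n_bins + 1)
    edges[-1] = np.inf  # raw_q == q_cap lands in the last bin
    raw = decoded["raw_q"].to_numpy()
    is_ncc = (decoded["category"] == CATEGORY_NEG_CODEWORD).to_numpy()
    is_gene = (decoded["category"] == CATEGORY_GENE).to_numpy()

    idx = np.clip(np.searchsorted(edges, raw, side="right") - 1, 0, n_bins - 1)
    n_total = np.bincount(idx, minlength=n_bins)
    n_ncc = np.bincount(idx[is_ncc], minlength=n_bins)
    n_gene = np.bincount(idx[is_gene], minlength=n_bins)

    # Merge sparse bins (< min_bin_calls) with their sparse neighbors: each
    # populated bin stands alone, and every maximal run of consecutive
    # sparse bins pools into one block. Populated (typically high-quality)
    # bins are never contaminated by stray calls from sparse ones.
    populated = n_total >= min_bin_calls
    starts = [0]
    for b in range(1, n_bins):
        if populated[b] or populated[b - 1]:
            starts.append(b)
    starts_arr = np.array(starts)
    block_of = np.searchsorted(starts_arr, np.arange(n_bins), side="right") - 1
    m = len(starts)
    n_total_m = np.array([n_total[block_of == i].sum() for i in range(m)])
    n_ncc_m = np.array([n_ncc[block_of == i].sum() for i in range(m)])
    n_gene_m = np.array([n_gene[block_of == i].sum() for i in range(m)])
    lo = edges[starts_arr]
    hi = np.append(lo[1:], edges[-1])

    rate = (n_ncc_m + 1.0) / n_ncc_codes
    fdr = np.minimum(1.0, rate * n_gene_codes / np.maximum(1, n_gene_m))
    with np.errstate(divide="ignore"):
        qv_bins = np.minimum(q_cap, -10.0 * np.log10(fdr))
    qv_bins = _pava_nondecreasing(qv_bins, np.maximum(n_total_m, 1).astype(float))
    # PAVA averaging can nudge a block past the cap boundary only downward,
    # but clip defensively
    qv_bins = np.clip(qv_bins, 0.0, q_cap)

    table = CalibrationTable(
        bin_edges=np.append(lo, hi[-1]),
        n_total=n_total_m,
        n_ncc=n_ncc_m,
        n_gene=n_gene_m,
        fdr=fdr,
        qv=qv_bins,
    )
    out = decoded.copy()
    out["qv"] = table.lookup(raw)
    return table, out


def apply_q_filter(
    decoded: pd.DataFrame, threshold: float = DEFAULT_Q_THRESHOLD
) -> pd.DataFrame:
    """Keep transcripts with calibrated qv >= threshold (order preserved)."""
    if decoded["qv"].isna().any():
        raise ValueError("qv not filled; run calibrate() first")
    return decoded[decoded["qv"] >= threshold].copy()
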