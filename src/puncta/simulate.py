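"""Forward simulator for targeted in situ transcriptomics.

Generates ground-truth tissues (non-overlapping disc cells with concentric
nuclei and cytoplasmic transcript clouds), per-punctum cycle x channel
optical signals under an on/off log-normal intensity model with bit-flip
noise, rendered image stacks, single-cell reference count matrices, and
landmark pairs for registration — everything the decoding / segmentation /
integration pipeline consumes, with the truth retained for evaluation.

The simulation is 2D (a single z-plane): the decoding and assignment math is
dimension-agnostic, so z coordinates are carried but zero. Cells are discs
and nuclei concentric discs, which is sufficient geometry for all
distance-based assignment contracts.

Background ("non-specific") puncta carry uniformly random bit patterns of
the codebook weight, so a fraction of them decode to negative-control
codewords — this is what makes the Q-score calibration testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codebook import Codebook, PROBE_CATEGORIES


@dataclass
class NoiseConfig:
    """Per-bit optical noise model used to corrupt codeword signals.

    Log-intensities of "on" bits are N(mu_on, sigma_on^2) and of "off" bits
    N(mu_off, sigma_off^2); intensities are their exponentials. Each on-bit
    drops out (reads as off) with ``p_dropout``; each off-bit lights up
    spuriously with ``p_spurious``.
    """

    mu_on: float = 4.0
    sigma_on: float = 0.3
    mu_off: float = 2.0
    sigma_off: float = 0.3
    p_dropout: float = 0.05
    p_spurious: float = 0.005

    def __post_init__(self) -> None:
        if self.mu_on <= self.mu_off:
            raise ValueError("mu_on must exceed mu_off")
        if self.sigma_on < 0 or self.sigma_off < 0:
            raise ValueError("sigmas must be nonnegative")


@dataclass
class CellType:
    name: str
    mean_expression: np.ndarray  # per gene, aligned to SimConfig.gene_names
    proportion: float


@dataclass
class SimConfig:
    """Study conditions for the forward simulation (units: micrometres)."""

    seed: int = 0
    field_size: tuple[float, float] = (400.0, 400.0)  # (x, y) um
    pixel_size: float = 0.2  # um / pixel (instrument-scale resolution)
    n_cells: int = 100
    gene_names: list[str] = field(default_factory=list)
    cell_types: list[CellType] = field(default_factory=list)
    nucleus_radius: tuple[float, float] = (4.0, 0.5)  # mean, sd um
    cell_radius: tuple[float, float] = (9.0, 1.0)  # mean, sd um
    transcripts_per_cell: tuple[float, float] = (166.0, 10.0)  # NB mean, dispersion
    background_rate: float = 5.0  # false puncta per 100x100 um
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    psf_sigma: float = 1.5  # pixels
    localization_jitter: float = 0.05  # um, isotropic Gaussian

    def __post_init__(self) -> None:
        if self.cell_types:
            total = sum(t.proportion for t in self.cell_types)
            if not np.isclose(total, 1.0):
                raise ValueError("cell type proportions must sum to 1")
        if self.background_rate < 0 or self.pixel_size <= 0:
            raise ValueError("rates and pixel size must be nonnegative/positive")


@dataclass
class GroundTruth:
    """Simulated tissue: cells table + transcripts table with source labels.

    ``cells`` columns: cell_id (1-based), cell_type, x, y, nucleus_radius,
    cell_radius. ``transcripts`` columns: gene, x, y, z, cell_id (0 =
    background punctum not originating from any cell).
    """

    cells: pd.DataFrame
    transcripts: pd.DataFrame

    def nucleus_label_image(self, field_size: tuple[float, float], pixel_size: float):
        """Rasterize nucleus discs into a NucleusLabelImage (labels = cell ids)."""
        from .segment import NucleusLabelImage

        w = int(np.ceil(field_size[0] / pixel_size))
        h = int(np.ceil(field_size[1] / pixel_size))
        labels = np.zeros((h, w), dtype=np.int32)
        # pixel centers in um
        xs = (np.arange(w) + 0.5) * pixel_size
        ys = (np.arange(h) + 0.5) * pixel_size
        for row in self.cells.itertuples():
            r = row.nucleus_radius
            ix = np.where(np.abs(xs - row.x) <= r)[0]
            iy = np.where(np.abs(ys - row.y) <= r)[0]
            if len(ix) == 0 or len(iy) == 0:
                continue
            dx = xs[ix] - row.x
            dy = ys[iy] - row.y
            disc = dy[:, None] ** 2 + dx[None, :] ** 2 <= r**2
            block = labels[np.ix_(iy, ix)]
            block[disc] = row.cell_id
            labels[np.ix_(iy, ix)] = block
        return NucleusLabelImage(labels=labels, pixel_size=pixel_size)


@dataclass
class Observations:
    """A batch of punctum observations as dense arrays.

    ``intensity`` is ``(n, n_cycles, n_channels)``; ``true_code`` holds the
    ground-truth codebook index per observation (-1 for random background
    bit patterns) and exists only for evaluation.
    """

    xyz: np.ndarray  # (n, 3) um
    intensity: np.ndarray  # (n, n_cycles, n_channels)
    true_code: np.ndarray  # (n,) int, -1 = background/random

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def subset(self, mask: np.ndarray) -> "Observations":
        return Observations(self.xyz[mask], self.intensity[mask], self.true_code[mask])


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial with mean/dispersion parameterization (var = m + m^2/r)."""
    mean = np.asarray(mean, dtype=float)
    out_shape = size if size is not None else mean.shape
    p = dispersion / (dispersion + mean)
    counts = np.zeros(np.broadcast_shapes(out_shape, mean.shape), dtype=np.int64)
    pos = np.broadcast_to(mean, counts.shape) > 0
    if pos.any():
        counts[pos] = rng.negative_binomial(dispersion, np.broadcast_to(p, counts.shape)[pos])
    return counts


def default_cell_types(
    gene_names: Sequence[str],
    n_types: int = 5,
    markers_per_type: int | None = None,
    marker_mean: float = 30.0,
    base_mean: float = 0.3,
    seed: int = 0,
) -> list[CellType]:
    """Well-separated expression profiles: disjoint marker blocks per type.

    Each type expresses a dedicated block of marker genes at ``marker_mean``
    counts/cell and everything else at ``base_mean`` — a caricature of the
    distinct epithelial / stromal / immune profiles targeted panels are
    designed around.
    """
    n_genes = len(gene_names)
    if markers_per_type is None:
        markers_per_type = max(1, n_genes // (2 * n_types))
    rng = np.random.default_rng(seed)
    props = np.full(n_types, 1.0 / n_types)
    types = []
    for t in range(n_types):
        mean = np.full(n_genes, base_mean)
        lo = t * markers_per_type
        mean[lo : lo + markers_per_type] = marker_mean
        types.append(CellType(name=f"type_{t}", mean_expression=mean, proportion=props[t]))
    # rng unused but kept for future profile randomization hooks
    del rng
    return types


def simulate_reference(
    config: SimConfig, n_ref_cells: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a dissociated single-cell reference (counts, labels).

    Per-cell gene counts are independent negative binomials around the
    cell-type mean (dispersion from ``transcripts_per_cell``). Returns a
    dense ``(n_ref_cells, n_genes)`` integer matrix and a string label array.
    """
    if not config.cell_types:
        raise ValueError("config.cell_types is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    props = np.array([t.proportion for t in config.cell_types])
    type_idx = rng.choice(len(config.cell_types), size=n_ref_cells, p=props)
    n_genes = len(config.gene_names)
    counts = np.zeros((n_ref_cells, n_genes), dtype=np.int64)
    dispersion = config.transcripts_per_cell[1]
    for t, ct in enumerate(config.cell_types):
        rows = np.where(type_idx == t)[0]
        if len(rows) == 0:
            continue
        counts[rows] = _nb_draw(
            rng, ct.mean_expression[None, :], dispersion, size=(len(rows), n_genes)
        )
    labels = np.array([config.cell_types[t].name for t in type_idx])
    return counts, labels


def simulate_tissue(
    config: SimConfig, codebook: Codebook | None = None, max_attempts: int = 20000
) -> GroundTruth:
    """Place non-overlapping disc cells and scatter their transcript clouds.

    Cell centers are rejection-sampled so discs neither overlap nor cross
    the field edge. Each cell draws a negative-binomial transcript count,
    genes from its type profile, and positions uniformly within its disc.
    Background puncta are a spatial Poisson process over the field at
    ``background_rate`` per 100x100 um, with nominal gene labels drawn
    uniformly from the probe-bearing codebook categories (their optical bit
    patterns are randomized later by :func:`simulate_signals`).
    """
    rng = np.random.default_rng(config.seed)
    fx, fy = config.field_size
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    nuc_radii: list[float] = []
    attempts = 0
    while len(centers) < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"placement failed: placed {len(centers)}/{config.n_cells} cells"
            )
        r = max(1.0, rng.normal(*config.cell_radius))
        rn = min(max(0.5, rng.normal(*config.nucleus_radius)), 0.9 * r)
        x = rng.uniform(r, fx - r)
        y = rng.uniform(r, fy - r)
        ok = all(
            (x - cx) ** 2 + (y - cy) ** 2 > (r + cr) ** 2
            for (cx, cy), cr in zip(centers, radii)
        )
        if ok:
            centers.append((x, y))
            radii.append(r)
            nuc_radii.append(rn)

    n_types = len(config.cell_types)
    if config.n_cells > 0 and n_types == 0:
        raise ValueError("config.cell_types is empty")
    props = np.array([t.proportion for t in config.cell_types]) if n_types else None
    type_idx = (
        rng.choice(n_types, size=config.n_cells, p=props)
        if config.n_cells
        else np.array([], dtype=int)
    )

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, config.n_cells + 1),
            "cell_type": [config.cell_types[t].name for t in type_idx],
            "x": [c[0] for c in centers],
            "y": [c[1] for c in centers],
            "nucleus_radius": nuc_radii,
            "cell_radius": radii,
        }
    )

    genes_all: list[str] = []
    tx: list[np.ndarray] = []
    ty: list[np.ndarray] = []
    tcell: list[np.ndarray] = []
    mean_n, disp = config.transcripts_per_cell
    gene_names = np.asarray(config.gene_names)
    for i in range(config.n_cells):
        n_tx = int(_nb_draw(rng, np.array(mean_n), disp, size=()))
        if n_tx == 0:
            continue
        profile = config.cell_types[type_idx[i]].mean_expression.astype(float)
        if profile.sum() <= 0:
            continue
        p = profile / profile.sum()
        g = rng.choice(len(gene_names), size=n_tx, p=p)
        # uniform in disc
        rr = radii[i] * np.sqrt(rng.uniform(size=n_tx))
        th = rng.uniform(0, 2 * np.pi, size=n_tx)
        genes_all.extend(gene_names[g])
        tx.append(centers[i][0] + rr * np.cos(th))
        ty.append(centers[i][1] + rr * np.sin(th))
        tcell.append(np.full(n_tx, i + 1, dtype=np.int64))

    # background false puncta
    lam = config.background_rate * (fx * fy) / 1e4
    n_bg = rng.poisson(lam) if lam > 0 else 0
    if n_bg > 0:
        if codebook is not None:
            probe_names = [
                n
                for n, c in zip(codebook.names, codebook.categories)
                if c in PROBE_CATEGORIES
            ]
        else:
            probe_names = list(gene_names)
        bg_genes = rng.choice(probe_names, size=n_bg) if probe_names else []
        genes_all.extend(bg_genes)
        tx.append(rng.uniform(0, fx, size=n_bg))
        ty.append(rng.uniform(0, fy, size=n_bg))
        tcell.append(np.zeros(n_bg, dtype=np.int64))

    if tx:
        transcripts = pd.DataFrame(
            {
                "gene": genes_all,
                "x": np.concatenate(tx),
                "y": np.concatenate(ty),
                "z": 0.0,
                "cell_id": np.concatenate(tcell),
            }
        )
    else:
        transcripts = pd.DataFrame(
            {"gene": [], "x": [], "y": [], "z": [], "cell_id": []}
        ).astype({"x": float, "y": float, "z": float, "cell_id": np.int64})
    return GroundTruth(cells=cells, transcripts=transcripts)


def simulate_signals(
    truth: GroundTruth,
    codebook: Codebook,
    config: SimConfig,
    seed: int | None = None,
) -> Observations:
    """Emit one noisy cycle x channel intensity matrix per transcript.

    Cell-derived transcripts start from their gene's codeword; background
    puncta (cell_id == 0) start from a uniformly random bit pattern of the
    codebook weight (true_code = -1). On-bits then drop out with p_dropout,
    off-bits light up with p_spurious, and per-bit intensities are drawn
    log-normally conditional on the realized bit state. Positions are
    jittered by isotropic Gaussian localization noise.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = truth.transcripts["gene"].to_numpy()
    cell_ids = truth.transcripts["cell_id"].to_numpy()
    n = len(genes)
    n_bits = codebook.n_bits
    flat = codebook.flat_codes()

    code_idx = np.empty(n, dtype=np.int64)
    for i, g in enumerate(genes):
        try:
            code_idx[i] = codebook.index_of(g)
        except KeyError:
            raise KeyError(f"unknown gene name {g!r} not in codebook") from None

    bits = flat[code_idx].astype(bool)
    bg = cell_ids == 0
    if bg.any():
        # random constant-weight patterns for non-specific background puncta
        n_bg = int(bg.sum())
        rand_bits = np.zeros((n_bg, n_bits), dtype=bool)
        for j in range(n_bg):
            rand_bits[j, rng.choice(n_bits, size=codebook.weight, replace=False)] = True
        bits[bg] = rand_bits

    noise = config.noise
    drop = rng.uniform(size=bits.shape) < noise.p_dropout
    spur = rng.uniform(size=bits.shape) < noise.p_spurious
    realized = (bits & ~drop) | (~bits & spur)

    log_i = np.where(
        realized,
        rng.normal(noise.mu_on, noise.sigma_on, size=bits.shape),
        rng.normal(noise.mu_off, noise.sigma_off, size=bits.shape),
    )
    intensity = np.exp(log_i).reshape(n, codebook.n_cycles, codebook.n_channels)

    xyz = truth.transcripts[["x", "y", "z"]].to_numpy(dtype=float).copy()
    if config.localization_jitter > 0 and n > 0:
        xyz[:, :2] += rng.normal(0, config.localization_jitter, size=(n, 2))

    true_code = code_idx.copy()
    true_code[bg] = -1
    return Observations(xyz=xyz, intensity=intensity, true_code=true_code)


def render_image_stack(
    observations: Observations,
    config: SimConfig,
    shot_noise: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Render observations as Gaussian puncta onto a (cycles, channels, H, W) stack.

    Each observation contributes, in every cycle/channel plane, an isotropic
    2D Gaussian of ``psf_sigma`` pixels whose total integrated signal equals
    that bit's intensity times ``2*pi*sigma^2`` (i.e. the intensity is the
    peak amplitude). Optional Poisson shot noise is applied per pixel.
    """
    if config.pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    fx, fy = config.field_size
    w = int(np.ceil(fx / config.pixel_size))
    h = int(np.ceil(fy / config.pixel_size))
    n = len(observations)
    n_cy, n_ch = observations.intensity.shape[1:] if n else (0, 0)
    if n == 0:
        return np.zeros((n_cy, n_ch, h, w), dtype=np.float64)

    sigma = config.psf_sigma
    halfw = max(3, int(np.ceil(4 * sigma)))
    k = 2 * halfw + 1
    stack = np.zeros((n_cy, n_ch, h, w), dtype=np.float64)

    px = observations.xyz[:, 0] / config.pixel_size - 0.5  # pixel-center coords
    py = observations.xyz[:, 1] / config.pixel_size - 0.5
    cx = np.clip(np.round(px).astype(int), 0, w - 1)
    cy = np.clip(np.round(py).astype(int), 0, h - 1)
    offs = np.arange(-halfw, halfw + 1)
    gx = np.exp(-((cx[:, None] + offs[None, :] - px[:, None]) ** 2) / (2 * sigma**2))
    gy = np.exp(-((cy[:, None] + offs[None, :] - py[:, None]) ** 2) / (2 * sigma**2))
    stamp = gy[:, :, None] * gx[:, None, :]  # (n, k, k)

    iy = cy[:, None, None] + offs[None, :, None]
    ix = cx[:, None, None] + offs[None, None, :]
    valid = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
    iy_f = np.broadcast_to(iy, (n, k, k))[valid]
    ix_f = np.broadcast_to(ix, (n, k, k))[valid]
    stamp_f = stamp[valid]
    obs_f = np.broadcast_to(np.arange(n)[:, None, None], (n, k, k))[valid]

    for c in range(n_cy):
        for ch in range(n_ch):
            amp = observations.intensity[:, c, ch]
            np.add.at(stack[c, ch], (iy_f, ix_f), stamp_f * amp[obs_f])

    if shot_noise:
        rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
        stack = rng.poisson(stack).astype(np.float64)
    return stack


def simulate_landmarks(
    transform,
    n: int,
    outlier_fraction: float = 0.0,
    jitter: float = 0.5,
    seed: int = 0,
    field_size: tuple[float, float] = (1000.0, 1000.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired landmark coordinates for registration testing.

    ``transform`` is a Transform or a 3x3 homogeneous matrix. Returns
    ``(src, dst, inlier_mask)``: inlier pairs satisfy dst = T(src) + Gaussian
    jitter; exactly ``round(outlier_fraction * n)`` pairs get uniformly
    random destinations instead.
    """
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must be in [0, 1)")
    if n < 2:
        raise ValueError("need at least 2 landmark pairs")
    from .integrate import Transform, apply_transform

    if not isinstance(transform, Transform):
        transform = Transform(model="affine", matrix=np.asarray(transform, dtype=float))
    rng = np.random.default_rng(seed)
    src = rng.uniform([0, 0], field_size, size=(n, 2))
    dst = apply_transform(transform, src)
    if jitter > 0:
        dst = dst + rng.normal(0, jitter, size=dst.shape)
    n_out = int(round(outlier_fraction * n))
    inlier = np.ones(n, dtype=bool)
    if n_out > 0:
        out_idx = rng.choice(n, size=n_out, replace=False)
        inlier[out_idx] = False
        dst[out_idx] = rng.uniform([0, 0], field_size, size=(n_out, 2))
    return src, dst, inlier


def make_sim_config(
    codebook: Codebook,
    n_types: int = 5,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Convenience: a SimConfig whose gene list and type profiles match a codebook."""
    gene_names = [
        n for n, c in zip(codebook.names, codebook.categories) if c == "gene"
    ]
    cfg = SimConfig(seed=seed, gene_names=gene_names, **overrides)
    cfg.cell_types = default_cell_types(gene_names, n_types=n_types, seed=seed)
    return cfg
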