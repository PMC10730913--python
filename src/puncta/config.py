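"""Flat run configuration shared by the CLI stages.

One namespace holds every stage parameter so a full pipeline run is
reproducible from a single plain-text YAML file plus the seed. Unknown keys
are rejected rather than ignored — a typo in a parameter name should fail
loudly, not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .codebook import build_codebook
from .simulate import NoiseConfig, SimConfig, make_sim_config


@dataclass
class RunConfig:
    seed: int = 0
    # codebook
    n_genes: int = 313
    n_neg_probe: int = 20
    n_neg_codeword: int = 40
    n_unassigned: int = 20
    n_cycles: int = 15
    n_channels: int = 4
    weight: int = 4
    min_hamming: int = 4
    # tissue / optics
    field_x: float = 400.0
    field_y: float = 400.0
    pixel_size: float = 0.2
    n_cells: int = 100
    n_types: int = 5
    transcripts_per_cell_mean: float = 166.0
    transcripts_per_cell_dispersion: float = 10.0
    background_rate: float = 5.0
    mu_on: float = 4.0
    sigma_on: float = 0.3
    mu_off: float = 2.0
    sigma_off: float = 0.3
    p_dropout: float = 0.05
    p_spurious: float = 0.005
    psf_sigma: float = 1.5
    # detection
    min_prominence: float = 10.0
    fit_window: int = 9
    max_sigma: float = 3.0
    # decoding / calibration
    q_cap: float = 40.0
    n_bins: int = 20
    q_threshold: float = 20.0
    # assignment
    max_expansion: float = 15.0
    # label transfer
    n_pcs: int = 50
    k_neighbors: int = 30
    majority: float = 0.5
    n_ref_cells: int = 2000
    # spots / registration
    spot_pitch: float = 100.0
    spot_diameter: float = 55.0
    inlier_tol: float = 5.0
    ransac_iter: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def build_codebook(self):
        return build_codebook(
            n_genes=self.n_genes,
            n_neg_probe=self.n_neg_probe,
            n_neg_codeword=self.n_neg_codeword,
            n_unassigned=self.n_unassigned,
            n_cycles=self.n_cycles,
            n_channels=self.n_channels,
            weight=self.weight,
            min_hamming=self.min_hamming,
            seed=self.seed,
        )

    def sim_config(self, codebook) -> SimConfig:
        cfg = make_sim_config(
            codebook,
            n_types=self.n_types,
            seed=self.seed,
            field_size=(self.field_x, self.field_y),
            pixel_size=self.pixel_size,
            n_cells=self.n_cells,
            transcripts_per_cell=(
                self.transcripts_per_cell_mean,
                self.transcripts_per_cell_dispersion,
            ),
            background_rate=self.background_rate,
            psf_sigma=self.psf_sigma,
            noise=NoiseConfig(
                mu_on=self.mu_on,
                sigma_on=self.sigma_on,
                mu_off=self.mu_off,
                sigma_off=self.sigma_off,
                p_dropout=self.p_dropout,
                p_spurious=self.p_spurious,
            ),
        )
        return cfg
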