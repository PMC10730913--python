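"""Shared fixtures: a small codebook for unit tests and a full-scale
simulated run (313-gene panel, ~10^4 puncta) reused by the heavier
end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

import puncta
from puncta.decode import NoiseModel


@pytest.fixture(scope="session")
def small_codebook():
    return puncta.build_codebook(
        n_genes=20,
        n_neg_probe=2,
        n_neg_codeword=5,
        n_unassigned=2,
        n_cycles=15,
        n_channels=4,
        weight=4,
        min_hamming=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def panel_codebook():
    """Full-size panel: 313 genes plus controls over 15 cycles x 4 channels."""
    return puncta.build_codebook(
        n_genes=313,
        n_neg_probe=20,
        n_neg_codeword=40,
        n_unassigned=20,
        n_cycles=15,
        n_channels=4,
        weight=4,
        min_hamming=4,
        seed=1,
    )


@pytest.fixture(scope="session")
def panel_run(panel_codebook):
    """One simulated tissue at the panel scale with signals at default noise.

    Returns a dict with the ground truth, observations, decoded table and
    calibrated transcripts — the standard conditions for the end-to-end
    correctness checks (~10^4 puncta from ~60 cells plus background).
    """
    cb = panel_codebook
    cfg = puncta.make_sim_config(
        cb,
        n_types=5,
        seed=1,
        n_cells=60,
        field_size=(300.0, 300.0),
        transcripts_per_cell=(166.0, 10.0),
    )
    truth = puncta.simulate_tissue(cfg, cb)
    obs = puncta.simulate_signals(truth, cb, cfg)
    model = NoiseModel.from_noise_config(cfg.noise)
    decoded = puncta.decode_ml(obs, cb, model)
    table, calibrated = puncta.calibrate(decoded, cb)
    return {
        "codebook": cb,
        "config": cfg,
        "truth": truth,
        "observations": obs,
        "model": model,
        "decoded": decoded,
        "table": table,
        "calibrated": calibrated,
    }


@pytest.fixture(scope="session")
def type_profiles():
    """Five well-separated expression profiles over 100 genes."""
    gene_names = [f"g{i:03d}" for i in range(100)]
    return gene_names, puncta.simulate.default_cell_types(gene_names, n_types=5)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
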