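"""Forward-simulator contracts: moments, containment, determinism,
noise-free limits, and the closed-form Gaussian/binomial checks."""

import numpy as np
import pytest

import puncta
from puncta.integrate import Transform
from puncta.simulate import NoiseConfig, default_cell_types


def _config(codebook, **over):
    defaults = dict(
        n_types=2,
        seed=7,
        n_cells=20,
        field_size=(150.0, 150.0),
        transcripts_per_cell=(50.0, 10.0),
    )
    defaults.update(over)
    return puncta.make_sim_config(codebook, **defaults)


class TestSimulateReference:
    def test_all_zero_profile_gives_zero_matrix(self, small_codebook):
        cfg = _config(small_codebook)
        cfg.cell_types = [
            puncta.simulate.CellType("null", np.zeros(len(cfg.gene_names)), 1.0)
        ]
        counts, labels = puncta.simulate_reference(cfg, 50)
        assert counts.sum() == 0
        assert set(labels) == {"null"}

    def test_sample_means_match_configured_means(self, small_codebook):
        cfg = _config(small_codebook)
        counts, labels = puncta.simulate_reference(cfg, 1000, seed=5)
        disp = cfg.transcripts_per_cell[1]
        for t in cfg.cell_types:
            rows = counts[labels == t.name]
            m = t.mean_expression
            se = np.sqrt((m + m**2 / disp) / len(rows))
            dev = np.abs(rows.mean(axis=0) - m)
            assert np.all(dev <= 3 * np.maximum(se, 1e-9) + 1e-9)

    def test_deterministic(self, small_codebook):
        cfg = _config(small_codebook)
        a, la = puncta.simulate_reference(cfg, 100)
        b, lb = puncta.simulate_reference(cfg, 100)
        assert np.array_equal(a, b) and np.array_equal(la, lb)


class TestSimulateTissue:
    def test_empty_truth(self, small_codebook):
        cfg = _config(small_codebook, n_cells=0, background_rate=0.0)
        truth = puncta.simulate_tissue(cfg, small_codebook)
        assert len(truth.cells) == 0 and len(truth.transcripts) == 0

    def test_transcripts_inside_cell_boundary(self, small_codebook):
        cfg = _config(small_codebook, n_cells=1, background_rate=0.0)
        truth = puncta.simulate_tissue(cfg, small_codebook)
        cell = truth.cells.iloc[0]
        tx = truth.transcripts
        d = np.hypot(tx["x"] - cell.x, tx["y"] - cell.y)
        assert (tx["cell_id"] == 1).all()
        assert (d <= cell.cell_radius + 1e-9).all()

    def test_mean_transcripts_per_cell(self, small_codebook):
        cfg = _config(
            small_codebook,
            n_cells=200,
            field_size=(700.0, 700.0),
            background_rate=0.0,
            transcripts_per_cell=(50.0, 10.0),
        )
        truth = puncta.simulate_tissue(cfg, small_codebook)
        per_cell = truth.transcripts.groupby("cell_id").size()
        mean, disp = cfg.transcripts_per_cell
        se = np.sqrt((mean + mean**2 / disp) / 200)
        assert abs(per_cell.mean() - mean) <= 3 * se

    def test_nuclei_disjoint(self, small_codebook):
        cfg = _config(small_codebook, n_cells=30, field_size=(250.0, 250.0))
        truth = puncta.simulate_tissue(cfg, small_codebook)
        c = truth.cells
        xy = c[["x", "y"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        rsum = c["cell_radius"].to_numpy()[:, None] + c["cell_radius"].to_numpy()[None, :]
        off = ~np.eye(len(c), dtype=bool)
        assert np.all(d[off] > rsum[off])

    def test_placement_failure_raises(self, small_codebook):
        cfg = _config(small_codebook, n_cells=500, field_size=(60.0, 60.0))
        with pytest.raises(RuntimeError, match="placement failed"):
            puncta.simulate_tissue(cfg, small_codebook, max_attempts=500)


class TestSimulateSignals:
    def test_noise_free_bits_match_codeword(self, small_codebook):
        cfg = _config(small_codebook, background_rate=0.0)
        cfg.noise = NoiseConfig(
            p_dropout=0.0, p_spurious=0.0, sigma_on=0.0, sigma_off=0.0
        )
        truth = puncta.simulate_tissue(cfg, small_codebook)
        obs = puncta.simulate_signals(truth, small_codebook, cfg)
        flat = small_codebook.flat_codes()
        thr = np.exp((cfg.noise.mu_on + cfg.noise.mu_off) / 2)
        bits = (obs.intensity.reshape(len(obs), -1) > thr).astype(np.uint8)
        assert np.array_equal(bits, flat[obs.true_code])

    def test_full_dropout_kills_on_bits(self, small_codebook):
        cfg = _config(small_codebook, background_rate=0.0)
        cfg.noise = NoiseConfig(p_dropout=1.0, p_spurious=0.0, sigma_on=0.0, sigma_off=0.0)
        truth = puncta.simulate_tissue(cfg, small_codebook)
        obs = puncta.simulate_signals(truth, small_codebook, cfg)
        thr = np.exp((cfg.noise.mu_on + cfg.noise.mu_off) / 2)
        assert not np.any(obs.intensity > thr)

    def test_dropout_fraction_binomial(self, small_codebook):
        # weight-4 codes at p_dropout=0.05: P(>=1 dropped bit) = 1 - 0.95^4
        cfg = _config(
            small_codebook,
            n_cells=100,
            field_size=(500.0, 500.0),
            background_rate=0.0,
            transcripts_per_cell=(100.0, 10.0),
        )
        cfg.noise = NoiseConfig(p_dropout=0.05, p_spurious=0.0, sigma_on=0.0, sigma_off=0.0)
        truth = puncta.simulate_tissue(cfg, small_codebook)
        obs = puncta.simulate_signals(truth, small_codebook, cfg)
        flat = small_codebook.flat_codes()
        thr = np.exp((cfg.noise.mu_on + cfg.noise.mu_off) / 2)
        bits = obs.intensity.reshape(len(obs), -1) > thr
        expected_on = flat[obs.true_code].astype(bool)
        dropped = (expected_on & ~bits).any(axis=1)
        p_expect = 1 - 0.95**4
        n = len(obs)
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(dropped.mean() - p_expect) <= 4 * se

    def test_count_conservation(self, panel_run):
        assert len(panel_run["observations"]) == len(panel_run["truth"].transcripts)

    def test_unknown_gene_raises(self, small_codebook):
        import pandas as pd

        cfg = _config(small_codebook)
        truth = puncta.GroundTruth(
            cells=pd.DataFrame(),
            transcripts=pd.DataFrame(
                {"gene": ["NOPE"], "x": [1.0], "y": [1.0], "z": [0.0], "cell_id": [1]}
            ),
        )
        with pytest.raises(KeyError, match="NOPE"):
            puncta.simulate_signals(truth, small_codebook, cfg)


class TestRenderImageStack:
    def test_no_observations_zero_stack(self, small_codebook):
        cfg = _config(small_codebook)
        obs = puncta.Observations(
            xyz=np.zeros((0, 3)), intensity=np.zeros((0, 15, 4)), true_code=np.zeros(0, int)
        )
        stack = puncta.render_image_stack(obs, cfg)
        npix = int(np.ceil(150.0 / cfg.pixel_size))
        assert stack.shape[2:] == (npix, npix) and not np.any(stack)

    def test_argmax_at_true_position(self, small_codebook):
        cfg = _config(small_codebook, field_size=(40.0, 40.0))
        intensity = np.full((1, 2, 2), 100.0)
        obs = puncta.Observations(
            xyz=np.array([[20.3, 31.7, 0.0]]), intensity=intensity, true_code=np.array([0])
        )
        stack = puncta.render_image_stack(obs, cfg)
        for c in range(2):
            for ch in range(2):
                r, col = np.unravel_index(np.argmax(stack[c, ch]), stack[c, ch].shape)
                x = (col + 0.5) * cfg.pixel_size
                y = (r + 0.5) * cfg.pixel_size
                assert abs(x - 20.3) <= cfg.pixel_size and abs(y - 31.7) <= cfg.pixel_size

    def test_integrated_gaussian_mass(self, small_codebook):
        # total rendered signal ~ amplitude * 2*pi*sigma^2, within 1%
        cfg = _config(small_codebook, field_size=(40.0, 40.0))
        amp = 50.0
        obs = puncta.Observations(
            xyz=np.array([[20.0, 20.0, 0.0]]),
            intensity=np.full((1, 1, 1), amp),
            true_code=np.array([0]),
        )
        stack = puncta.render_image_stack(obs, cfg)
        expected = amp * 2 * np.pi * cfg.psf_sigma**2
        assert abs(stack.sum() - expected) / expected < 0.01


class TestSimulateLandmarks:
    def test_identity_no_jitter(self):
        t = Transform.similarity()
        src, dst, inl = puncta.simulate_landmarks(t, 50, jitter=0.0, seed=0)
        assert np.allclose(src, dst) and inl.all()

    def test_exact_outlier_count(self):
        t = Transform.similarity(rotation_deg=2.58)
        src, dst, inl = puncta.simulate_landmarks(
            t, 100, outlier_fraction=0.3, jitter=0.5, seed=1
        )
        assert inl.sum() == 70
        resid = np.linalg.norm(puncta.apply_transform(t, src) - dst, axis=1)
        assert np.all(resid[inl] <= 3 * 0.5 * np.sqrt(2) + 1e-6)

    def test_deterministic(self):
        t = Transform.similarity(rotation_deg=1.0, translation=(5, 5))
        a = puncta.simulate_landmarks(t, 60, outlier_fraction=0.2, seed=9)
        b = puncta.simulate_landmarks(t, 60, outlier_fraction=0.2, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


def test_pseudobulk_proportions_converge(small_codebook):
    """Law of large numbers: simulated per-gene pseudobulk fractions approach
    the mixture-weighted configured profile."""
    gene_names = [
        n for n, c in zip(small_codebook.names, small_codebook.categories) if c == "gene"
    ]
    types = default_cell_types(gene_names, n_types=2, seed=3)
    cfg = puncta.SimConfig(
        seed=3, gene_names=gene_names, cell_types=types,
        transcripts_per_cell=(100.0, 10.0),
    )
    counts, labels = puncta.simulate_reference(cfg, 1000, seed=4)
    total = counts.sum()
    observed = counts.sum(axis=0) / total
    # condition on the realized type counts; remaining variance is NB only
    disp = cfg.transcripts_per_cell[1]
    n_by_type = {t.name: (labels == t.name).sum() for t in types}
    expected_totals = sum(n_by_type[t.name] * t.mean_expression for t in types)
    expected = expected_totals / expected_totals.sum()
    var_totals = sum(
        n_by_type[t.name] * (t.mean_expression + t.mean_expression**2 / disp)
        for t in types
    )
    se = np.sqrt(var_totals) / expected_totals.sum()
    assert np.all(np.abs(observed - expected) <= 4 * se + 1e-4)
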