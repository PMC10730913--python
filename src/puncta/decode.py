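"""Maximum-likelihood codeword decoding with Phred-style raw quality.

Each punctum carries one intensity per cycle/channel bit. Under the noise
model, the log-intensity of a bit is Gaussian with state-dependent
parameters (on: mu_on/sigma_on, off: mu_off/sigma_off) and bits are
independent, so the log-likelihood of a codeword is a sum of per-bit Gaussian
log-densities. The decoder scores every codeword in the codebook — genes,
negative-control probes, negative-control codewords and unassigned codes
alike, under a uniform prior — takes the argmax, and converts the softmax
posterior of the winner into a Phred-scaled raw quality,

    raw_q = min(q_cap, -10 * log10(1 - p_best)),

which is subsequently recalibrated bin-wise against negative-control
codeword rates (see :mod:`puncta.qcal`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .codebook import Codebook
from .simulate import Observations

INTENSITY_FLOOR = 1e-6
DEFAULT_Q_CAP = 40.0


@dataclass
class NoiseModel:
    """Gaussian log-intensity parameters for on/off bit states."""

    mu_on: float
    sigma_on: float
    mu_off: float
    sigma_off: float

    def __post_init__(self) -> None:
        if self.sigma_on <= 0 or self.sigma_off <= 0:
            raise ValueError("sigmas must be positive")
        if self.mu_on <= self.mu_off:
            raise ValueError("mu_on must exceed mu_off")

    @classmethod
    def from_noise_config(cls, noise) -> "NoiseModel":
        """Adopt the generating parameters of a simulation NoiseConfig."""
        return cls(
            mu_on=noise.mu_on,
            sigma_on=max(noise.sigma_on, 1e-3),
            mu_off=noise.mu_off,
            sigma_off=max(noise.sigma_off, 1e-3),
        )

    @classmethod
    def estimate(cls, intensity: np.ndarray) -> "NoiseModel":
        """Two-component moment-matching fit from observed intensities.

        Splits log-intensities at Otsu-like midpoint (mean of the two
        k-means-style cluster means found by thresholding at the overall
        mean, iterated to convergence) and takes per-side moments.
        """
        y = np.log(np.maximum(np.asarray(intensity, float).ravel(), INTENSITY_FLOOR))
        thr = y.mean()
        for _ in range(50):
            lo, hi = y[y <= thr], y[y > thr]
            if len(lo) == 0 or len(hi) == 0:
                break
            new = 0.5 * (lo.mean() + hi.mean())
            if abs(new - thr) < 1e-9:
                break
            thr = new
        lo, hi = y[y <= thr], y[y > thr]
        return cls(
            mu_on=float(hi.mean()),
            sigma_on=float(max(hi.std(), 1e-3)),
            mu_off=float(lo.mean()),
            sigma_off=float(max(lo.std(), 1e-3)),
        )


def _per_bit_loglik(log_intensity: np.ndarray, model: NoiseModel):
    """Return (ll_off, ll_on) per-bit Gaussian log densities, any shape."""
    ll_on = -0.5 * ((log_intensity - model.mu_on) / model.sigma_on) ** 2 - np.log(
        model.sigma_on * np.sqrt(2 * np.pi)
    )
    ll_off = -0.5 * ((log_intensity - model.mu_off) / model.sigma_off) ** 2 - np.log(
        model.sigma_off * np.sqrt(2 * np.pi)
    )
    return ll_off, ll_on


def loglik_code(intensity: np.ndarray, code: np.ndarray, model: NoiseModel) -> float:
    """Log-likelihood of one observation's intensity matrix under one codeword.

    Sums, over all cycle/channel bits, the Gaussian log-density of the
    observed log-intensity under the bit state the codeword prescribes.
    """
    intensity = np.asarray(intensity, dtype=float)
    code = np.asarray(code)
    if intensity.shape != code.shape:
        raise ValueError(
            f"intensity shape {intensity.shape} != code shape {code.shape}"
        )
    y = np.log(np.maximum(intensity, INTENSITY_FLOOR))
    ll_off, ll_on = _per_bit_loglik(y, model)
    return float(np.where(code == 1, ll_on, ll_off).sum())


def loglik_matrix(
    intensity: np.ndarray, codebook: Codebook, model: NoiseModel
) -> np.ndarray:
    """Log-likelihood of every observation under every codeword.

    ``intensity``: (n_obs, n_cycles, n_channels). Returns (n_obs, n_codes).
    Uses the identity ll(code) = sum(ll_off) + code . (ll_on - ll_off) so the
    scan over the codebook is a single matrix product.
    """
    n = intensity.shape[0]
    y = np.log(np.maximum(intensity.reshape(n, -1), INTENSITY_FLOOR))
    ll_off, ll_on = _per_bit_loglik(y, model)
    base = ll_off.sum(axis=1)  # (n,)
    delta = ll_on - ll_off  # (n, n_bits)
    codes = codebook.flat_codes().astype(float)  # (n_codes, n_bits)
    return base[:, None] + delta @ codes.T


def decode_ml(
    observations: Observations,
    codebook: Codebook,
    model: NoiseModel,
    q_cap: float = DEFAULT_Q_CAP,
) -> pd.DataFrame:
    """Decode each observation to its maximum-likelihood codeword.

    All codebook entries, including negative-control and unassigned
    codewords, compete under a uniform prior. The winner's softmax posterior
    p_best gives raw_q = min(q_cap, -10*log10(1 - p_best)). Ties are broken
    toward the lowest code index (np.argmax convention).

    Returns a transcript table with columns: code_id, feature, category,
    x, y, z, raw_q, qv (NaN until calibration), cell_id (0 until
    assignment), true_code (simulation bookkeeping).
    """
    if codebook.n_codes == 0:
        raise ValueError("empty codebook")
    ll = loglik_matrix(observations.intensity, codebook, model)
    best = np.argmax(ll, axis=1)
    # posterior of the winner under a uniform prior
    log_post = ll - logsumexp(ll, axis=1, keepdims=True)
    p_best = np.exp(log_post[np.arange(len(best)), best])
    with np.errstate(divide="ignore"):
        raw_q = -10.0 * np.log10(np.maximum(1.0 - p_best, 1e-300))
    raw_q = np.minimum(raw_q, q_cap)

    names = np.asarray(codebook.names, dtype=object)
    cats = np.asarray(codebook.categories, dtype=object)
    return pd.DataFrame(
        {
            "code_id": best,
            "feature": names[best],
            "category": cats[best],
            "x": observations.xyz[:, 0],
            "y": observations.xyz[:, 1],
            "z": observations.xyz[:, 2],
            "raw_q": raw_q,
            "qv": np.nan,
            "cell_id": 0,
            "true_code": observations.true_code,
        }
    )
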