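"""Punctum detection and sub-pixel Gaussian fitting on image stacks.

A punctum is a diffraction-limited point source — smaller than a pixel —
so its image is the microscope PSF, well approximated by an isotropic 2D
Gaussian. Candidates are local maxima on the max-projection of the stack
across cycles and channels (one detection per amplified product; per-bit
intensities are then sampled from each plane). Each candidate is refined by
least-squares fitting of amplitude, center, and width within a local
window; fits that do not converge or whose width exceeds ``max_sigma`` are
discarded as non-punctate (autofluorescent blobs, debris).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .simulate import Observations


@dataclass
class RawPunctum:
    """One detected point source with sub-pixel position (um)."""

    x: float
    y: float
    intensity: np.ndarray  # (n_cycles, n_channels), window-integrated, >= 0
    fit_quality: float  # residual norm of the Gaussian fit
    footprint_sigma: float  # fitted PSF sigma, pixels


def _gauss2d(params, yy, xx):
    amp, cy, cx, sigma, offset = params
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)) + offset


def _fit_gaussian(window: np.ndarray, sigma0: float):
    """LSQ fit of an isotropic Gaussian + offset; returns params or None."""
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # local background: median of the window perimeter
    perim = np.concatenate(
        [window[0, :], window[-1, :], window[1:-1, 0], window[1:-1, -1]]
    )
    offset0 = float(np.median(perim))
    amp0 = max(float(window.max()) - offset0, 1e-6)
    p0 = [amp0, (h - 1) / 2.0, (w - 1) / 2.0, sigma0, offset0]

    def resid(p):
        return (_gauss2d(p, yy, xx) - window).ravel()

    try:
        res = least_squares(
            resid,
            p0,
            bounds=(
                [0.0, -1.0, -1.0, 0.2, -np.inf],
                [np.inf, h, w, max(h, w), np.inf],
            ),
            max_nfev=200,
        )
    except ValueError:
        return None
    if not res.success:
        return None
    return res.x, float(np.linalg.norm(res.fun))


def detect_puncta(
    stack: np.ndarray,
    pixel_size: float,
    min_prominence: float,
    fit_window: int = 9,
    max_sigma: float = 3.0,
    sigma0: float = 1.5,
    min_separation: int = 2,
) -> list[RawPunctum]:
    """Detect puncta on a (cycles, channels, H, W) stack.

    Candidates are local maxima of the across-cycle/channel max-projection
    standing at least ``min_prominence`` above the local background (median
    of the fit-window perimeter). Each is refined by a 2D Gaussian fit in a
    ``fit_window`` x ``fit_window`` patch; candidates with fitted sigma >
    ``max_sigma`` pixels or failed fits are dropped. Per-bit intensities are
    the background-subtracted sums over the patch in every plane, floored
    at a small positive value.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must be (cycles, channels, H, W)")
    if stack.size == 0:
        raise ValueError("empty stack")
    if fit_window < 3:
        raise ValueError("fit_window must be >= 3")
    if np.min(stack) < 0:
        raise ValueError("stack must be nonnegative")

    n_cy, n_ch, h, w = stack.shape
    proj = stack.reshape(-1, h, w).max(axis=0)
    half = fit_window // 2

    coords = peak_local_max(
        proj, min_distance=min_separation, threshold_abs=float(np.min(proj))
    )
    out: list[RawPunctum] = []
    for r, c in coords:
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        win = proj[r0:r1, c0:c1]
        perim = np.concatenate(
            [win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]]
        )
        background = float(np.median(perim))
        if proj[r, c] - background < min_prominence:
            continue
        fit = _fit_gaussian(win, sigma0)
        if fit is None:
            continue
        (amp, cy, cx, sigma, offset), residual = fit
        if sigma > max_sigma or amp <= 0:
            continue
        # window-integrated per-plane intensity, background-subtracted
        planes = stack[:, :, r0:r1, c0:c1]
        plane_bg = np.median(
            np.concatenate(
                [
                    planes[:, :, 0, :],
                    planes[:, :, -1, :],
                    planes[:, :, 1:-1, 0],
                    planes[:, :, 1:-1, -1],
                ],
                axis=2,
            ),
            axis=2,
        )
        integ = planes.sum(axis=(2, 3)) - plane_bg * win.size
        intensity = np.maximum(integ, 1e-6)
        out.append(
            RawPunctum(
                x=float((c0 + cx + 0.5) * pixel_size),
                y=float((r0 + cy + 0.5) * pixel_size),
                intensity=intensity,
                fit_quality=residual,
                footprint_sigma=float(sigma),
            )
        )
    return out


def puncta_to_observations(puncta: list[RawPunctum]) -> Observations:
    """Pack detections into the batch container the decoder consumes."""
    if not puncta:
        return Observations(
            xyz=np.zeros((0, 3)),
            intensity=np.zeros((0, 0, 0)),
            true_code=np.zeros(0, dtype=int),
        )
    xyz = np.array([[p.x, p.y, 0.0] for p in puncta])
    intensity = np.stack([p.intensity for p in puncta])
    return Observations(
        xyz=xyz, intensity=intensity, true_code=np.full(len(puncta), -1, dtype=int)
    )
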