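"""Quantitative evaluation of denoising results.

Scalar accuracy (mean-normalized error), PSNR per b-shell, SNR maps,
noise-floor measurement in free-water regions, normalized residual maps with
structure-preservation shape statistics, and the tractography connection
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvalResult",
    "normalized_error",
    "psnr",
    "estimate_snr_map",
    "noise_floor",
    "floor_ratio",
    "residual_map",
    "residual_shape_stats",
    "tractography_score",
]


@dataclass
class EvalResult:
    """Bundle of evaluation outputs for one denoising condition."""

    error: float
    psnr_per_b: dict = field(default_factory=dict)
    noise_floor: float | None = None
    snr_map: np.ndarray | None = None


def normalized_error(denoised, truth, mask=None, rel_threshold: float = 1e-6):
    """Mean-normalized absolute difference to the noise-free ground truth.

    ``mean over voxels and volumes of |S_hat - S| / S`` within ``mask``.
    Voxels where the truth is at or below ``rel_threshold * max(truth)`` are
    excluded (the division is unstable where the true signal vanishes, e.g.
    free water at high b); the exclusion count is reported via a warning.
    """
    denoised = np.asarray(denoised, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if denoised.shape != truth.shape:
        raise ValueError("denoised and truth shapes differ")
    if mask is None:
        sel = np.ones(truth.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        sel = np.broadcast_to(mask[..., None] if mask.ndim == truth.ndim - 1 else mask, truth.shape).copy()
    guard = rel_threshold * truth.max()
    bad = sel & (truth <= guard)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"excluding {n_bad} voxel-volume samples with vanishing ground truth",
            stacklevel=2,
        )
        sel &= truth > guard
    if not sel.any():
        raise ValueError("no valid samples for the normalized error")
    return float(np.mean(np.abs(denoised[sel] - truth[sel]) / truth[sel]))


def psnr(denoised, truth, mask=None, bvals=None):
    """Peak signal-to-noise ratio ``10 log10(1 / MSE)`` in dB.

    Both images are scaled by the truth's peak so MSE is a true peak ratio.
    With ``bvals`` the PSNR is computed per b-shell (volumes grouped by
    rounding to the nearest 50 s/mm^2) and a dict ``{b: dB}`` is returned;
    otherwise a single float.
    """
    denoised = np.asarray(denoised, dtype=float)
    truth = np.asarray(truth, dtype=float)
    peak = truth.max()
    if peak <= 0:
        raise ValueError("ground truth has no signal")
    d = denoised / peak
    t = truth / peak
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)

    def _mse(dv, tv):
        if mask is not None:
            dv, tv = dv[mask], tv[mask]
        return float(np.mean((dv - tv) ** 2))

    if bvals is None:
        mse = _mse(d, t)
        return float(10.0 * np.log10(1.0 / mse)) if mse > 0 else np.inf
    bvals = np.asarray(bvals, dtype=float)
    shells = np.round(bvals / 50.0) * 50.0
    out = {}
    for b in np.unique(shells):
        idx = shells == b
        mse = _mse(d[..., idx], t[..., idx])
        out[float(b)] = float(10.0 * np.log10(1.0 / mse)) if mse > 0 else np.inf
    return out


def estimate_snr_map(image, noise_sigma_map):
    """Voxel-wise SNR: mean magnitude over volumes divided by the noise level.

    Noise-free voxels (``sigma = 0``) are flagged with an ``inf`` sentinel.
    """
    image = np.asarray(image)
    sigma = np.asarray(noise_sigma_map, dtype=float)
    signal = np.mean(np.abs(image), axis=-1) if image.ndim == sigma.ndim + 1 else np.abs(image)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sigma > 0, signal / np.where(sigma > 0, sigma, 1.0), np.inf)
    return snr


def noise_floor(image, region_mask, bvals, b_select: float | None = None):
    """Mean magnitude over a free-water region at the highest b-value.

    In regions of unhindered diffusion the true signal at strong diffusion
    weighting is essentially zero, so whatever mean magnitude remains is the
    (Rician/noncentral-chi) noise floor.
    """
    image = np.asarray(image)
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("noise-floor region mask is empty")
    bvals = np.asarray(bvals, dtype=float)
    b = bvals.max() if b_select is None else float(b_select)
    vols = np.isclose(bvals, b)
    if not vols.any():
        raise ValueError(f"no volumes at b={b}")
    return float(np.mean(np.abs(image[mask][:, vols])))


def floor_ratio(noisy, denoised, region_mask, bvals, b_select: float | None = None):
    """Fold-reduction of the noise floor: ``floor(noisy) / floor(denoised)``."""
    return noise_floor(noisy, region_mask, bvals, b_select) / noise_floor(
        denoised, region_mask, bvals, b_select
    )


def residual_map(before, after, sigma_map=None):
    """Noise-normalized residual ``(before - after) / sigma`` per voxel."""
    before = np.asarray(before)
    after = np.asarray(after)
    res = before - after
    if sigma_map is not None:
        sigma = np.asarray(sigma_map, dtype=float)
        while sigma.ndim < res.ndim:
            sigma = sigma[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = np.where(sigma > 0, res / np.where(sigma > 0, sigma, 1.0), 0.0)
    return res


def residual_shape_stats(residual, min_samples: int = 10_000):
    """Skewness and excess kurtosis of the residuals.

    Gaussian-shaped residuals (both statistics near zero) indicate the
    denoiser removed noise rather than structure.
    """
    flat = np.asarray(residual, dtype=float).ravel()
    flat = flat[np.isfinite(flat)]
    if flat.size < min_samples:
        raise ValueError(f"need at least {min_samples} residual samples, got {flat.size}")
    return float(stats.skew(flat)), float(stats.kurtosis(flat))


def tractography_score(vc: float, ic: float, nc: float) -> float:
    """Connection score ``1 - sqrt((VC-1)^2 + IC^2 + NC^2) / sqrt(2)``.

    ``VC``, ``IC`` and ``NC`` are the valid-, invalid- and no-connection
    streamline fractions; the score is 1 for a perfect tractogram
    (``VC = 1``) and 0 when every streamline is invalid or unconnected.
    """
    for name, val in (("VC", vc), ("IC", ic), ("NC", nc)):
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    return 1.0 - np.sqrt((vc - 1.0) ** 2 + ic**2 + nc**2) / np.sqrt(2.0)
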