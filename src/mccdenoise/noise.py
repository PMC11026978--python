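"""Noise-level estimation and channel noise-covariance handling.

Two noise estimators are provided for the block matrices fed to the
shrinkers:

* :func:`estimate_sigma_median` — the median singular value divided by the
  square root of ``N`` times the Marchenko-Pastur median.  Robust to a small
  number of signal spikes, and the default for all OS/TSVD/hard/soft
  strategies.
* :func:`estimate_sigma_mp` — the bulk-mean estimator obtained jointly with
  the signal count from the MP fit; used by the MP-PCA strategies.

Channel noise in multi-coil data is correlated; :func:`whiten_channels`
applies the Mahalanobis transform ``Phi^{-1/2}`` along the channel axis so
the i.i.d.-Gaussian assumption of random-matrix theory holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

from .shrinkage import EigenSpectrum, SingularSpectrum, mp_pca_fit

__all__ = [
    "NoiseModel",
    "mp_support",
    "mp_median",
    "estimate_sigma_median",
    "estimate_sigma_mp",
    "estimate_channel_cov",
    "whiten_channels",
    "unwhiten_channels",
    "read_channel_cov",
    "write_channel_cov",
]


@dataclass
class NoiseModel:
    """Per-voxel noise level and (optional) channel covariance."""

    sigma_map: np.ndarray
    channel_cov: np.ndarray | None = None
    whitened: bool = False

    def __post_init__(self):
        if np.any(np.asarray(self.sigma_map) < 0):
            raise ValueError("sigma_map must be non-negative")
        if self.channel_cov is not None:
            _validate_cov(np.asarray(self.channel_cov))


def mp_support(delta: float) -> tuple[float, float]:
    """Support edges ``(1 -/+ sqrt(delta))**2`` of the MP law (unit variance)."""
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must lie in (0, 1], got {delta}")
    r = np.sqrt(delta)
    return (1.0 - r) ** 2, (1.0 + r) ** 2


@lru_cache(maxsize=None)
def mp_median(delta: float) -> float:
    """Median of the Marchenko-Pastur distribution with aspect ratio delta.

    Solves ``integral_{lo}^{mu} sqrt((hi - x)(x - lo)) / (2 pi delta x) dx = 1/2``
    by bracketed root finding; as ``delta -> 0`` the law collapses to a point
    mass at 1 and the median tends to 1.
    """
    lo, hi = mp_support(delta)

    def density(x):
        return np.sqrt(max((hi - x) * (x - lo), 0.0)) / (2.0 * np.pi * delta * x)

    def cdf_minus_half(u):
        val, _ = integrate.quad(density, lo, u, limit=200, epsabs=1e-10)
        return val - 0.5

    eps = 1e-10 * (hi - lo)
    return float(optimize.brentq(cdf_minus_half, lo + eps, hi - eps, xtol=1e-10))


def estimate_sigma_median(spec: SingularSpectrum) -> float:
    """Noise level from the median singular value.

    ``sigma_hat = s_median / sqrt(n * mu_half(delta))`` where ``mu_half`` is
    the MP median.  Because at most ``m/2`` signal spikes can move the median,
    the estimate is insensitive to a few strong signal components.
    """
    if spec.m < 3:
        raise ValueError("need at least 3 singular values for the median estimator")
    s_med = float(np.median(spec.values))
    # numerically-zero bulk (noise-free rank-deficient input) maps to sigma 0
    if s_med <= 1e-6 * spec.values[0]:
        return 0.0
    return s_med / np.sqrt(spec.n * mp_median(spec.aspect))


def estimate_sigma_mp(spec: SingularSpectrum) -> tuple[float, int]:
    """Noise level and signal count from the simultaneous MP fit."""
    p, sigma = mp_pca_fit(EigenSpectrum.from_singular(spec))
    return sigma, p


def _validate_cov(phi: np.ndarray) -> None:
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError(f"covariance must be square, got shape {phi.shape}")
    if not np.allclose(phi, phi.conj().T, atol=1e-10 * max(1.0, float(np.abs(phi).max()))):
        raise ValueError("covariance must be Hermitian")


def estimate_channel_cov(data: np.ndarray, background_mask: np.ndarray) -> np.ndarray:
    """Sample channel noise covariance from background (signal-free) voxels.

    ``data`` is a complex ``(x, y, z, c, v)`` array and ``background_mask`` a
    boolean spatial mask.  All masked voxels across all volumes contribute one
    complex channel vector each.  Near-singular estimates (condition number
    above 1e8) are ridge-regularized by ``1e-6 * trace / C``.
    """
    data = np.asarray(data)
    mask = np.asarray(background_mask, dtype=bool)
    c = data.shape[3]
    n_vox = int(mask.sum())
    if n_vox < 10 * c:
        raise ValueError(
            f"background mask selects {n_vox} voxels; need at least {10 * c} (10 per channel)"
        )
    # samples: (n_vox * V, C)
    samples = data[mask].transpose(0, 2, 1).reshape(-1, c)
    samples = samples - samples.mean(axis=0, keepdims=True)
    phi = (samples.conj().T @ samples) / (samples.shape[0] - 1)
    phi = 0.5 * (phi + phi.conj().T)
    eigvals = np.linalg.eigvalsh(phi)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], np.finfo(float).tiny) > 1e8:
        phi = phi + (1e-6 * np.trace(phi).real / c) * np.eye(c)
    return phi


def _cov_sqrt_factors(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hermitian ``Phi^{-1/2}`` and ``Phi^{1/2}`` via eigendecomposition."""
    _validate_cov(phi)
    w, u = np.linalg.eigh(phi)
    if w[0] <= 0:
        raise ValueError(
            f"covariance is not positive definite: smallest eigenvalue {w[0]:.3e}"
        )
    inv_sqrt = (u * (1.0 / np.sqrt(w))) @ u.conj().T
    sqrt = (u * np.sqrt(w)) @ u.conj().T
    return inv_sqrt, sqrt


def _apply_channel_matrix(data: np.ndarray, mat: np.ndarray) -> np.ndarray:
    # data (x,y,z,c,v), mat (c,c): out[..., c, v] = sum_c' mat[c, c'] data[..., c', v]
    return np.einsum("ab,xyzbv->xyzav", mat, data, optimize=True)


def whiten_channels(data: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Mahalanobis channel decorrelation ``S <- Phi^{-1/2} S``."""
    inv_sqrt, _ = _cov_sqrt_factors(np.asarray(phi))
    return _apply_channel_matrix(np.asarray(data), inv_sqrt)


def unwhiten_channels(data: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`whiten_channels` (``S <- Phi^{1/2} S``)."""
    _, sqrt = _cov_sqrt_factors(np.asarray(phi))
    return _apply_channel_matrix(np.asarray(data), sqrt)


def read_channel_cov(path, imag_path=None) -> np.ndarray:
    """Read a CxC covariance from plain-text matrix file(s).

    A single file holds a real matrix; a second file supplies the imaginary
    part for complex covariances.
    """
    phi = np.loadtxt(path, dtype=float)
    if imag_path is not None:
        phi = phi + 1j * np.loadtxt(imag_path, dtype=float)
    phi = np.atleast_2d(phi)
    _validate_cov(phi)
    return phi


def write_channel_cov(phi: np.ndarray, path, imag_path=None) -> None:
    """Write a covariance as plain text (real part; imaginary part optional)."""
    phi = np.asarray(phi)
    np.savetxt(path, phi.real)
    if np.iscomplexobj(phi) and imag_path is not None:
        np.savetxt(imag_path, phi.imag)
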