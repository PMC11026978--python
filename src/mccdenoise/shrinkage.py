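"""Singular-value shrinkage for low-rank matrix recovery.

All shrinkers operate in normalized units ``y = s / (sigma * sqrt(N))`` for an
``M x N`` matrix (``M <= N``) with i.i.d. Gaussian noise of standard deviation
``sigma``.  In these units the Marchenko-Pastur bulk of a pure-noise matrix
occupies ``[1 - sqrt(delta), 1 + sqrt(delta)]`` with aspect ratio
``delta = M / N``, so every threshold below is expressed relative to the bulk
edge ``1 + sqrt(delta)``.

Seven strategies are provided:

``mp_pca``
    Marchenko-Pastur PCA: fit the noise bulk, keep the ``P`` supra-bulk
    components *unchanged* (no debiasing).
``tsvd``
    Truncated SVD at the bulk edge.
``hard``
    Hard thresholding at the asymptotically optimal level ``y_dagger(delta)``.
``soft``
    Soft thresholding: subtract the bulk edge from retained values.
``fro``, ``op``, ``nuc``
    Optimal shrinkage minimizing, respectively, the Frobenius, operator and
    nuclear norm of the recovery error (Gavish-Donoho style debiasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STRATEGIES",
    "SingularSpectrum",
    "EigenSpectrum",
    "ShrinkageResult",
    "normalize_spectrum",
    "z_transform",
    "shrink_fro",
    "shrink_op",
    "shrink_nuc",
    "shrink_tsvd",
    "hard_threshold_level",
    "shrink_hard",
    "shrink_soft",
    "shrink_values",
    "mp_pca_fit",
    "mp_pca_shrink",
    "recover_matrix",
    "denoise_matrix",
]

STRATEGIES = ("mp_pca", "tsvd", "hard", "soft", "fro", "op", "nuc")

#: strategies whose shrinkers act on noise-normalized singular values
OS_FAMILY = ("tsvd", "hard", "soft", "fro", "op", "nuc")


@dataclass(frozen=True)
class SingularSpectrum:
    """Singular values of an ``m x n`` matrix, sorted descending, ``m <= n``."""

    values: np.ndarray
    m: int
    n: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.m > self.n:
            raise ValueError(f"require m <= n, got m={self.m}, n={self.n}")
        if values.shape != (self.m,):
            raise ValueError(f"expected {self.m} singular values, got {values.shape}")
        if np.any(values < 0):
            raise ValueError("singular values must be non-negative")
        if np.any(np.diff(values) > 1e-12 * max(1.0, values[0] if len(values) else 0.0)):
            raise ValueError("singular values must be sorted in descending order")

    @property
    def aspect(self) -> float:
        """Aspect ratio delta = m/n in (0, 1]."""
        return self.m / self.n

    @classmethod
    def from_matrix(cls, s_mn: np.ndarray) -> "SingularSpectrum":
        m, n = s_mn.shape
        if m > n:
            s_mn = s_mn.T
            m, n = n, m
        return cls(np.linalg.svd(s_mn, compute_uv=False), m, n)


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues ``lambda_i = s_i**2`` of the sample covariance, descending."""

    eigenvalues: np.ndarray
    m: int
    n: int
    signal_count: int = 0

    def __post_init__(self):
        if not (0 <= self.signal_count < max(self.m, 1)):
            raise ValueError("signal_count must satisfy 0 <= P < M")

    @property
    def gamma(self) -> float:
        return (self.m - self.signal_count) / self.n

    @classmethod
    def from_singular(cls, spec: SingularSpectrum, signal_count: int = 0) -> "EigenSpectrum":
        return cls(spec.values**2, spec.m, spec.n, signal_count)


@dataclass(frozen=True)
class ShrinkageResult:
    """Shrunk singular values (same scale as the input spectrum)."""

    shrunk_values: np.ndarray
    sigma_used: float
    strategy: str
    rank: int = field(init=False)

    def __post_init__(self):
        values = np.asarray(self.shrunk_values, dtype=float)
        object.__setattr__(self, "shrunk_values", values)
        object.__setattr__(self, "rank", int(np.count_nonzero(values)))


def normalize_spectrum(spec: SingularSpectrum, sigma: float) -> np.ndarray:
    """Map singular values to noise units ``y = s / (sigma * sqrt(n))``.

    For a pure-noise matrix the largest ``y`` concentrates at the bulk edge
    ``1 + sqrt(delta)``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return spec.values / (sigma * np.sqrt(spec.n))


def _bulk_edge(delta: float) -> float:
    return 1.0 + np.sqrt(delta)


def _check_delta(delta: float) -> None:
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must lie in (0, 1], got {delta}")


def z_transform(y, delta: float):
    """Debiased singular value: the asymptotic signal level behind observed y.

    ``z(y) = sqrt((y^2 - delta - 1 + sqrt((y^2 - delta - 1)^2 - 4 delta)) / 2)``
    for ``y >= 1 + sqrt(delta)`` and 0 below the bulk edge.  At the edge
    ``z = delta**(1/4)``.
    """
    _check_delta(delta)
    y = np.asarray(y, dtype=float)
    above = y >= _bulk_edge(delta)
    t = y**2 - delta - 1.0
    # analytically >= 0 above the edge; clamp rounding underflow
    disc = np.maximum(t**2 - 4.0 * delta, 0.0)
    z = np.sqrt(np.maximum(t + np.sqrt(disc), 0.0) / 2.0)
    return np.where(above, z, 0.0)[()]


def shrink_fro(y, delta: float):
    """Optimal shrinker for the Frobenius-norm loss."""
    _check_delta(delta)
    y = np.asarray(y, dtype=float)
    above = y >= _bulk_edge(delta)
    t = y**2 - delta - 1.0
    disc = np.maximum(t**2 - 4.0 * delta, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.sqrt(disc) / y
    return np.where(above, np.where(y > 0, eta, 0.0), 0.0)[()]


def shrink_op(y, delta: float):
    """Optimal shrinker for the operator-norm loss (identical to ``z``)."""
    return z_transform(y, delta)


def shrink_nuc(y, delta: float):
    """Optimal shrinker for the nuclear-norm loss (most aggressive OS variant)."""
    _check_delta(delta)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z_transform(y, delta))
    num = z**4 - delta - np.sqrt(delta) * y * z
    keep = (z > 0) & (num >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = num / (z**2 * y)
    return np.where(keep, eta, 0.0)[()]


def shrink_tsvd(y, delta: float):
    """Truncation at the Marchenko-Pastur bulk edge; retained values unchanged."""
    _check_delta(delta)
    y = np.asarray(y, dtype=float)
    return np.where(y >= _bulk_edge(delta), y, 0.0)[()]


def hard_threshold_level(delta: float) -> float:
    """Optimal hard-threshold level ``y_dagger``; always above the bulk edge."""
    _check_delta(delta)
    return float(
        np.sqrt(
            2.0 * (delta + 1.0)
            + 8.0 * delta / ((delta + 1.0) + np.sqrt(delta**2 + 14.0 * delta + 1.0))
        )
    )


def shrink_hard(y, delta: float):
    """Hard thresholding at ``y_dagger(delta)``."""
    y = np.asarray(y, dtype=float)
    return np.where(y >= hard_threshold_level(delta), y, 0.0)[()]


def shrink_soft(y, delta: float):
    """Soft thresholding: subtract the bulk edge from retained values."""
    _check_delta(delta)
    y = np.asarray(y, dtype=float)
    edge = _bulk_edge(delta)
    return np.where(y >= edge, y - edge, 0.0)[()]


_SHRINKERS = {
    "tsvd": shrink_tsvd,
    "hard": shrink_hard,
    "soft": shrink_soft,
    "fro": shrink_fro,
    "op": shrink_op,
    "nuc": shrink_nuc,
}


def shrink_values(y, delta: float, strategy: str):
    """Apply the named shrinker (any OS-family strategy) in y-units."""
    if strategy not in _SHRINKERS:
        raise ValueError(f"unknown shrinkage strategy {strategy!r}; choose from {OS_FAMILY}")
    return _SHRINKERS[strategy](y, delta)


def mp_pca_fit(eig: EigenSpectrum) -> tuple[int, float]:
    """Simultaneous estimation of signal count P and noise level sigma.

    Scans P upward and accepts the smallest P for which the residual bulk
    ``lambda_{P+1} .. lambda_M`` is consistent with a Marchenko-Pastur
    distribution: the spread-implied noise variance
    ``(lambda_{P+1} - lambda_M) / (4 sqrt(gamma) N)`` must not exceed the
    bulk-mean variance ``sum(bulk) / ((M - P) N)``, with
    ``gamma = (M - P)/N``.  A bulk of identical *positive* eigenvalues is not
    a valid MP bulk (the MP law of any positive sigma has positive width) and
    is skipped, so noise-free input cannot be consumed as noise.

    Returns ``(P, sigma_hat)``.  An all-zero bulk accepts with ``sigma = 0``;
    if no consistent bulk exists the search is capped at ``P = M - 1`` with
    ``sigma = 0`` (the degenerate, effectively noise-free branch).
    """
    lam = np.asarray(eig.eigenvalues, dtype=float)
    m, n = eig.m, eig.n
    if m < 2:
        raise ValueError("need at least 2 eigenvalues for an MP fit")
    if lam[0] <= 0:
        return 0, 0.0
    best = None  # (spread/mean consistency ratio, p, sigma)
    for p in range(m - 1):
        bulk = lam[p:]
        if bulk[0] <= 0:
            return p, 0.0
        spread = bulk[0] - bulk[-1]
        if spread <= 1e-12 * lam[0]:
            continue  # repeated positive eigenvalue: not an MP bulk
        gamma = (m - p) / n
        sigma_sq_spread = spread / (4.0 * np.sqrt(gamma) * n)
        sigma_sq_mean = bulk.sum() / ((m - p) * n)
        if sigma_sq_spread <= sigma_sq_mean:
            return p, float(np.sqrt(sigma_sq_mean))
        ratio = sigma_sq_spread / sigma_sq_mean
        if best is None or ratio < best[0]:
            best = (ratio, p, float(np.sqrt(sigma_sq_mean)))
    if best is not None:
        # no bulk matches the MP width exactly (e.g. the noise level varies
        # within the block); fall back to the most MP-consistent bulk
        return best[1], best[2]
    return m - 1, 0.0


def mp_pca_shrink(spec: SingularSpectrum) -> ShrinkageResult:
    """MP-PCA denoising of a spectrum: keep the P supra-bulk values unchanged.

    Unlike the optimal shrinkers the retained values are *not* debiased; the
    signal components stay noise-inflated.  When no MP-consistent noise bulk
    exists (noise-free input) all values are retained.
    """
    p, sigma = mp_pca_fit(EigenSpectrum.from_singular(spec))
    shrunk = np.zeros_like(spec.values)
    if p == spec.m - 1 and sigma == 0.0 and spec.values[-1] > 0:
        # degenerate branch: no noise bulk found, nothing attributable to noise
        shrunk = spec.values.copy()
    else:
        shrunk[:p] = spec.values[:p]
    return ShrinkageResult(shrunk, sigma_used=sigma, strategy="mp_pca")


def recover_matrix(u: np.ndarray, v: np.ndarray, result: ShrinkageResult) -> np.ndarray:
    """Rebuild the denoised matrix ``U diag(shrunk) V`` from SVD factors.

    ``u`` is ``m x m`` and ``v`` is ``m x n`` (the leading right singular
    vectors as rows, as returned by ``np.linalg.svd(..., full_matrices=False)``).
    Identity shrinkage reproduces the input to machine precision.
    """
    m = result.shrunk_values.shape[0]
    if u.shape[1] != m or v.shape[0] != m:
        raise ValueError(
            f"factor shapes {u.shape}, {v.shape} incompatible with {m} singular values"
        )
    return (u * result.shrunk_values) @ v


def denoise_matrix(
    s_mn: np.ndarray,
    strategy: str,
    sigma: float | None = None,
) -> tuple[np.ndarray, ShrinkageResult]:
    """Denoise a single real matrix with the named strategy.

    For OS-family strategies ``sigma`` may be given; if omitted it is
    estimated with the median-based estimator.  ``mp_pca`` always estimates
    its own noise level.  The matrix is transposed internally if needed so
    that ``m <= n``; the output matches the input orientation.
    """
    from .noise import estimate_sigma_median  # local import avoids a cycle

    a = np.asarray(s_mn, dtype=float)
    transposed = a.shape[0] > a.shape[1]
    if transposed:
        a = a.T
    m, n = a.shape
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    spec = SingularSpectrum(s, m, n)

    if strategy == "mp_pca":
        result = mp_pca_shrink(spec)
    elif strategy in OS_FAMILY:
        if sigma is None:
            sigma = estimate_sigma_median(spec)
        if sigma == 0:
            # noise-free input passes through unchanged
            result = ShrinkageResult(s.copy(), sigma_used=0.0, strategy=strategy)
        else:
            y = normalize_spectrum(spec, sigma)
            eta = shrink_values(y, spec.aspect, strategy)
            result = ShrinkageResult(
                sigma * np.sqrt(n) * np.asarray(eta), sigma_used=sigma, strategy=strategy
            )
    else:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")

    out = recover_matrix(u, vt, result)
    if transposed:
        out = out.T
    return out, result
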