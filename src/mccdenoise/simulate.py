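"""Synthetic multi-channel complex dMRI phantom.

The generator recreates the statistical structure of a multi-coil diffusion
acquisition entirely in silico: a geometric phantom of fiber bundles
(anisotropic single-tensor compartments) and free-water regions, modulated by
smooth complex coil-sensitivity maps, a bidimensional-sinusoid background
phase with abrupt inter-slice jumps, and spatially varying complex Gaussian
noise (higher in the image center, SNR spanning 2-15).  The noisy signal per
voxel ``x``, channel ``c`` and volume ``v`` is

    S~_c(x,v) = R_c(x) S(x,v) exp(i phi_bg(x,v)) + eps_r + i eps_i,

with ``eps ~ N(0, sigma(x)^2)`` i.i.d. over voxels, channels, volumes and
real/imaginary parts.  Ground truth (noise-free channel signal, sensitivity
maps, phase, noise map, compartment labels) is returned alongside, so every
pipeline stage can be scored against it.

Compartment parameters: fibers have parallel diffusivity 1.7e-3 mm^2/s and
perpendicular diffusivity 0.4e-3 mm^2/s; free-water (CSF-like) regions have
isotropic diffusivity 3.0e-3 mm^2/s.  The default protocol holds 5 b=0
volumes plus 24/48/96 diffusion-weighted volumes at b = 1000/2000/3000 s/mm^2
(173 volumes total).

A small planted-spike matrix generator for rank-1 recovery experiments is
also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .pipeline import MccImage

__all__ = [
    "FiberBundle",
    "IsotropicRegion",
    "PhantomConfig",
    "PhantomTruth",
    "DIFFUSIVITY_PARALLEL",
    "DIFFUSIVITY_PERPENDICULAR",
    "DIFFUSIVITY_ISO",
    "PROTOCOL_BVALUES",
    "PROTOCOL_COUNTS",
    "tensor_signal",
    "isotropic_signal",
    "make_protocol",
    "make_sensitivity_maps",
    "make_background_phase",
    "make_noise_map",
    "compartment_labels",
    "noise_free_signal",
    "simulate_mcc",
    "default_phantom",
    "planted_spike_matrix",
]

# single-tensor compartment diffusivities, mm^2/s
DIFFUSIVITY_PARALLEL = 1.7e-3
DIFFUSIVITY_PERPENDICULAR = 0.4e-3
DIFFUSIVITY_ISO = 3.0e-3

# b-shells (s/mm^2) and volume counts: 5 + 24 + 48 + 96 = 173 volumes
PROTOCOL_BVALUES = (0.0, 1000.0, 2000.0, 3000.0)
PROTOCOL_COUNTS = (5, 24, 48, 96)

LABEL_BACKGROUND, LABEL_FIBER, LABEL_CROSSING, LABEL_ISO = 0, 1, 2, 3


@dataclass(frozen=True)
class FiberBundle:
    """Straight cylindrical fiber bundle: a point on the axis, a direction
    (normalized on construction) and a radius, all in voxel units."""

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("bundle direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / nrm))
        if self.radius <= 0:
            raise ValueError("bundle radius must be positive")

    def mask(self, grid: np.ndarray) -> np.ndarray:
        p = np.asarray(self.point)
        d = np.asarray(self.direction)
        rel = grid - p
        along = rel @ d
        perp = rel - along[..., None] * d
        return np.linalg.norm(perp, axis=-1) <= self.radius


@dataclass(frozen=True)
class IsotropicRegion:
    """Spherical free-diffusion region (CSF-like by default)."""

    center: tuple[float, float, float]
    radius: float
    diffusivity: float = DIFFUSIVITY_ISO

    def __post_init__(self):
        if self.radius <= 0 or self.diffusivity <= 0:
            raise ValueError("radius and diffusivity must be positive")

    def mask(self, grid: np.ndarray) -> np.ndarray:
        return np.linalg.norm(grid - np.asarray(self.center), axis=-1) <= self.radius


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    channels: int = 8
    bundles: list = field(default_factory=list)
    isotropic_regions: list = field(default_factory=list)
    bvalues: tuple = PROTOCOL_BVALUES
    shell_counts: tuple = PROTOCOL_COUNTS
    d_parallel: float = DIFFUSIVITY_PARALLEL
    d_perpendicular: float = DIFFUSIVITY_PERPENDICULAR
    snr_range: tuple[float, float] = (2.0, 15.0)
    phase_amplitude: float = math.pi / 2  # rad
    phase_frequency: tuple[float, float] = (1.5, 1.5)  # cycles per FOV
    seed: int = 0

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("need at least one channel")
        if len(self.bvalues) != len(self.shell_counts):
            raise ValueError("bvalues and shell_counts must align")
        if min(self.d_parallel, self.d_perpendicular) <= 0:
            raise ValueError("diffusivities must be positive")
        if not (0 < self.snr_range[0] <= self.snr_range[1]):
            raise ValueError("snr_range must satisfy 0 < lo <= hi")

    @property
    def n_volumes(self) -> int:
        return int(sum(self.shell_counts))


@dataclass
class PhantomTruth:
    """Everything the simulator knows: the keys to score a denoiser against."""

    signal: np.ndarray  # channel-free S(x, v), real
    noise_free: np.ndarray  # R_c(x) S(x, v), complex (x,y,z,c,v)
    sensitivity: np.ndarray  # R_c(x), complex (x,y,z,c)
    phase: np.ndarray  # phi_bg(x, v), real (x,y,z,v)
    sigma_map: np.ndarray  # sigma(x), real (x,y,z)
    labels: np.ndarray  # compartment labels, int (x,y,z)
    bvals: np.ndarray
    bvecs: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    @property
    def csf_mask(self) -> np.ndarray:
        return self.labels == LABEL_ISO


def tensor_signal(orientation, bval, bvec, d_parallel=DIFFUSIVITY_PARALLEL,
                  d_perpendicular=DIFFUSIVITY_PERPENDICULAR):
    """Single-tensor attenuation ``exp(-b (D_perp + (D_par - D_perp)(g.u)^2))``."""
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    g = np.asarray(bvec, dtype=float)
    cos2 = (g @ u) ** 2
    return np.exp(-np.asarray(bval) * (d_perpendicular + (d_parallel - d_perpendicular) * cos2))


def isotropic_signal(bval, d_iso=DIFFUSIVITY_ISO):
    """Monoexponential free-diffusion attenuation ``exp(-b D)``."""
    return np.exp(-np.asarray(bval) * d_iso)


def _sphere_points(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral hemisphere, standard for
    diffusion gradient tables)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = i / n  # upper hemisphere
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_protocol(bvalues=PROTOCOL_BVALUES, shell_counts=PROTOCOL_COUNTS):
    """FSL-convention b-value and gradient tables for the shell scheme."""
    bvals, bvecs = [], []
    for b, count in zip(bvalues, shell_counts):
        bvals.extend([b] * count)
        if b == 0:
            bvecs.extend([[0.0, 0.0, 0.0]] * count)
        else:
            bvecs.extend(_sphere_points(count).tolist())
    return np.asarray(bvals), np.asarray(bvecs)


def make_sensitivity_maps(channels: int, grid_shape, seed=0, amplitude_span: float | None = None) -> np.ndarray:
    """Smooth complex coil-sensitivity maps.

    One Gaussian lobe per channel, centered on a ring around the field of
    view with alternating z offsets, plus a gentle per-channel linear phase.
    The root-sum-of-squares magnitude is renormalized to a smooth radial
    envelope rising from the FOV center to the periphery by a factor
    ``amplitude_span`` (coils sit at the surface, so the combined amplitude
    is lowest at the center); strictly positive everywhere and 1 at the FOV
    center.  ``amplitude_span=None`` keeps the raw lobe profile.
    """
    shape = tuple(grid_shape)
    if channels == 1:
        return np.ones(shape + (1,), dtype=complex)
    rng = np.random.default_rng(seed)
    grid = _voxel_grid(shape)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    ring_r = 0.75 * max(shape) / 2.0
    width = 0.25 * max(shape)
    maps = np.empty(shape + (channels,), dtype=complex)
    for c in range(channels):
        ang = 2.0 * np.pi * c / channels + rng.uniform(-0.1, 0.1)
        pos = center + np.array(
            [ring_r * np.cos(ang), ring_r * np.sin(ang), ((-1) ** c) * 0.25 * shape[2]]
        )
        dist2 = np.sum((grid - pos) ** 2, axis=-1)
        amp = np.exp(-dist2 / (2.0 * width**2))
        k = rng.uniform(-0.05, 0.05, size=3)  # rad/voxel linear phase
        phase = grid @ k + rng.uniform(0, 2 * np.pi)
        maps[..., c] = amp * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=-1))
    if amplitude_span is not None:
        r = np.linalg.norm(grid - center, axis=-1)
        envelope = np.exp(np.log(amplitude_span) * r / r.max())
        maps = maps * (envelope / sos)[..., None]
        sos = envelope
    center_idx = tuple(int(round(ci)) for ci in center)
    return maps / sos[center_idx]


def make_background_phase(grid_shape, n_volumes: int, seed=0,
                          amplitude: float = math.pi / 2,
                          frequency=(1.5, 1.5)) -> np.ndarray:
    """Bidimensional-sinusoid background phase with per-slice random shifts.

    ``phi(x, y, z, v) = A sin(2 pi f_x x / X + psi_zv) sin(2 pi f_y y / Y + chi_zv)``
    — smooth within a slice, discontinuous across slices and volumes,
    mimicking intra-slice coil/physiology phase and abrupt inter-slice jumps.
    """
    nx, ny, nz = grid_shape
    rng = np.random.default_rng(seed)
    psi = rng.uniform(0, 2 * np.pi, size=(nz, n_volumes))
    chi = rng.uniform(0, 2 * np.pi, size=(nz, n_volumes))
    xs = np.arange(nx)[:, None, None, None]
    ys = np.arange(ny)[None, :, None, None]
    fx, fy = frequency
    phi = amplitude * np.sin(2 * np.pi * fx * xs / nx + psi[None, None]) * np.sin(
        2 * np.pi * fy * ys / ny + chi[None, None]
    )
    return phi


def make_noise_map(grid_shape, snr_range=(2.0, 15.0), amplitude=None, support=None) -> np.ndarray:
    """Spatially varying noise level: high in the center, low at the edges.

    ``sigma(x) = c (1 + g exp(-(r/w)^2))`` is a smooth radial bump centered on
    the grid; the gain ``g`` and scale ``c`` are solved so the realized b=0
    SNR ``amplitude(x) / sigma(x)`` spans exactly ``snr_range`` over the
    ``support`` mask (coil-amplitude variation carries part of the span, so
    the noise level itself varies gently on the scale of a denoising block).
    ``amplitude`` defaults to 1 everywhere and ``support`` to the whole grid.
    """
    lo, hi = snr_range
    if not (0 < lo <= hi):
        raise ValueError("snr_range must satisfy 0 < lo <= hi")
    shape = tuple(grid_shape)
    if np.isinf(lo):  # infinite SNR: noise-free acquisition
        return np.zeros(shape)
    amp = np.ones(shape) if amplitude is None else np.asarray(amplitude, dtype=float)
    sup = np.ones(shape, dtype=bool) if support is None else np.asarray(support, dtype=bool)
    if not sup.any():
        raise ValueError("empty support mask")
    grid = _voxel_grid(shape)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    r = np.linalg.norm(grid - center, axis=-1)
    if hi == lo:
        return amp / lo
    target = hi / lo
    a_sup = amp[sup]

    # widest (gentlest) radial bump that can still realize the span the coil
    # amplitudes do not already provide; keeps the noise level slowly varying
    # on the scale of a denoising block wherever the geometry allows
    g, bump = 0.0, np.ones_like(r)
    if a_sup.max() / a_sup.min() < target:
        for w_frac in (0.75, 0.5, 0.35, 0.25, 0.15):
            bump = np.exp(-((r / (w_frac * r.max())) ** 2))
            f_sup = bump[sup]

            def span(g_):
                snr_raw = a_sup / (1.0 + g_ * f_sup)
                return snr_raw.max() / snr_raw.min()

            if span(1e9) < target:
                continue
            g_hi = 1.0
            while span(g_hi) < target:
                g_hi *= 2.0
            g = float(optimize.brentq(lambda x: span(x) - target, 0.0, g_hi, xtol=1e-10))
            break
        else:
            raise ValueError("cannot realize the requested SNR span with this geometry")
    f_sup = bump[sup]
    scale = (a_sup / (1.0 + g * f_sup)).max() / hi
    return scale * (1.0 + g * bump)


def _voxel_grid(shape) -> np.ndarray:
    axes = [np.arange(s, dtype=float) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def compartment_labels(config: PhantomConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Label map plus the individual bundle masks (for crossing bookkeeping)."""
    grid = _voxel_grid(config.grid_shape)
    labels = np.zeros(config.grid_shape, dtype=int)
    bundle_masks = [b.mask(grid) for b in config.bundles]
    fiber_count = np.zeros(config.grid_shape, dtype=int)
    for mask in bundle_masks:
        fiber_count += mask
    labels[fiber_count == 1] = LABEL_FIBER
    labels[fiber_count >= 2] = LABEL_CROSSING
    for region in config.isotropic_regions:
        labels[region.mask(grid) & (fiber_count == 0)] = LABEL_ISO
    return labels, bundle_masks


def noise_free_signal(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Channel-free signal S(x, v) with compartment mixing in crossings.

    Crossing voxels average the single-tensor signals of the bundles passing
    through them (equal volume fractions).  Returns
    ``(signal, labels, bvals, bvecs)``.
    """
    bvals, bvecs = make_protocol(config.bvalues, config.shell_counts)
    labels, bundle_masks = compartment_labels(config)
    v = len(bvals)
    signal = np.zeros(config.grid_shape + (v,), dtype=float)
    grid = _voxel_grid(config.grid_shape)

    fiber_count = np.zeros(config.grid_shape, dtype=int)
    for mask in bundle_masks:
        fiber_count += mask
    for bundle, mask in zip(config.bundles, bundle_masks):
        if not mask.any():
            continue
        att = np.array(
            [
                tensor_signal(bundle.direction, b, g, config.d_parallel, config.d_perpendicular)
                for b, g in zip(bvals, bvecs)
            ]
        )
        frac = np.where(fiber_count[mask] > 0, 1.0 / fiber_count[mask], 0.0)
        signal[mask] += frac[:, None] * att[None, :]
    for region in config.isotropic_regions:
        mask = region.mask(grid) & (fiber_count == 0)
        att = isotropic_signal(bvals, region.diffusivity)
        signal[mask] = att[None, :]
    return signal, labels, bvals, bvecs


def simulate_mcc(config: PhantomConfig) -> tuple[MccImage, PhantomTruth]:
    """Generate one noisy multi-channel complex acquisition plus ground truth.

    Deterministic for a fixed config (independent random streams for
    sensitivities, phase and noise are spawned from the root seed).
    """
    ss = np.random.SeedSequence(config.seed)
    seed_sens, seed_phase, seed_noise = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    signal, labels, bvals, bvecs = noise_free_signal(config)
    maps = make_sensitivity_maps(config.channels, config.grid_shape, seed=seed_sens)
    if config.channels > 1:
        # calibrate the combined coil amplitude to a smooth radial envelope
        # rising outward across the support, so it carries most of the SNR
        # span and the noise level itself stays gently varying (as on a
        # full-scale grid, where a denoising block sees a near-constant sigma)
        lo_snr, hi_snr = config.snr_range
        if np.isfinite(lo_snr) and hi_snr > lo_snr:
            grid = _voxel_grid(config.grid_shape)
            center = (np.asarray(config.grid_shape, dtype=float) - 1) / 2.0
            r = np.linalg.norm(grid - center, axis=-1)
            sup = labels != LABEL_BACKGROUND
            r0, r1 = r[sup].min(), r[sup].max()
            span_a = (hi_snr / lo_snr) / 1.15  # leave ~15% of the span to sigma
            t = np.clip((r - r0) / max(r1 - r0, 1e-9), 0.0, 1.0)
            envelope = np.exp(np.log(span_a) * t)
            sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=-1))
            maps = maps * (envelope / sos)[..., None]
    phase = make_background_phase(
        config.grid_shape,
        len(bvals),
        seed=seed_phase,
        amplitude=config.phase_amplitude,
        frequency=config.phase_frequency,
    )
    amplitude_b0 = np.sqrt(np.sum(np.abs(maps) ** 2, axis=-1))  # S0 = 1 in support
    sigma_map = make_noise_map(
        config.grid_shape,
        config.snr_range,
        amplitude=amplitude_b0,
        support=labels != LABEL_BACKGROUND,
    )

    noise_free = maps[:, :, :, :, None] * signal[:, :, :, None, :]
    rng = np.random.default_rng(seed_noise)
    shape = noise_free.shape
    eps = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    noisy = noise_free * np.exp(1j * phase[:, :, :, None, :]) + sigma_map[..., None, None] * eps

    truth = PhantomTruth(
        signal=signal,
        noise_free=noise_free,
        sensitivity=maps,
        phase=phase,
        sigma_map=sigma_map,
        labels=labels,
        bvals=bvals,
        bvecs=bvecs,
    )
    image = MccImage(noisy, bvals=bvals, bvecs=bvecs)
    return image, truth


def default_phantom(scale: str = "mini", channels: int | None = None, seed: int = 0,
                    phase_amplitude: float | None = None) -> PhantomConfig:
    """Stock phantom configurations.

    ``mini`` — a 16^3 grid with one straight bundle, one crossing pair and a
    CSF-like sphere, full 173-volume protocol: the desk-scale test bed.
    ``full`` — 27 size-varying bundles (straight, bent and crossing
    configurations on a 48^3 grid) and 3 isotropic regions, 173 volumes.
    """
    kwargs = {}
    if channels is not None:
        kwargs["channels"] = channels
    if phase_amplitude is not None:
        kwargs["phase_amplitude"] = phase_amplitude
    if scale == "mini":
        # 1.5 cycles across a full-scale (~140 voxel) FOV scaled to this grid,
        # so a denoising block sees the same intra-slice phase gradient
        kwargs.setdefault("phase_frequency", (1.5 * 16 / 140.0,) * 2)
        bundles = [
            FiberBundle(point=(0.0, 4.5, 8.0), direction=(1, 0, 0), radius=2.2),
            FiberBundle(point=(10.5, 0.0, 4.5), direction=(0, 1, 0), radius=2.0),
            FiberBundle(point=(10.5, 8.5, 0.0), direction=(0, 0, 1), radius=2.0),
        ]
        regions = [IsotropicRegion(center=(4.0, 11.5, 11.5), radius=3.0)]
        return PhantomConfig(
            grid_shape=(16, 16, 16),
            bundles=bundles,
            isotropic_regions=regions,
            seed=seed,
            **kwargs,
        )
    if scale == "full":
        grid = (48, 48, 48)
        rng = np.random.default_rng(seed)
        bundles = []
        # 3 x 3 grid of bundle triplets: straight, obliquely bent pair, crossing
        for i in range(27):
            gx, gy = divmod(i % 9, 3)
            layer = i // 9
            base = np.array([8.0 + 16.0 * gx, 8.0 + 16.0 * gy, 8.0 + 16.0 * layer])
            axis = np.zeros(3)
            axis[i % 3] = 1.0
            tilt = rng.uniform(-0.35, 0.35, size=3) * (i % 2)  # alternate straight/oblique
            direction = axis + tilt
            radius = 1.5 + 1.5 * rng.uniform()
            bundles.append(FiberBundle(point=tuple(base), direction=tuple(direction), radius=radius))
        regions = [
            IsotropicRegion(center=(12.0, 36.0, 12.0), radius=4.0),
            IsotropicRegion(center=(36.0, 12.0, 36.0), radius=4.0),
            IsotropicRegion(center=(24.0, 24.0, 40.0), radius=3.5),
        ]
        kwargs.setdefault("phase_frequency", (1.5 * 48 / 140.0,) * 2)
        return PhantomConfig(
            grid_shape=grid,
            bundles=bundles,
            isotropic_regions=regions,
            seed=seed,
            **kwargs,
        )
    raise ValueError(f"scale must be 'mini' or 'full', got {scale!r}")


def planted_spike_matrix(size: int, spike: float, sigma: float, seed=0):
    """Rank-1 signal matrix plus i.i.d. Gaussian noise.

    The truth is ``spike * u v^T`` with random unit vectors, so its only
    non-zero singular value is ``spike``.  Returns ``(noisy, truth)``.
    """
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(size)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(size)
    v /= np.linalg.norm(v)
    truth = spike * np.outer(u, v)
    noisy = truth + sigma * rng.standard_normal((size, size))
    return noisy, truth
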