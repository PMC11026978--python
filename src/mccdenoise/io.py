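"""NIfTI / text readers and writers and run manifests.

Complex images are stored as two float32 NIfTI files (real/imaginary or
magnitude/phase) for interoperability; the canonical in-memory layout is a
5-D complex array indexed ``(x, y, z, channel, volume)`` (dim4 = channel,
dim5 = volume).  Protocols follow the FSL ``.bval``/``.bvec`` text
convention; channel covariances are plain-text matrices.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .pipeline import MccImage

__all__ = [
    "read_mcc",
    "write_mcc",
    "read_protocol",
    "write_protocol",
    "write_nifti",
    "read_nifti",
    "write_outputs",
]


def _load_5d(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None, None]
    elif data.ndim == 4:
        data = data[:, :, :, None, :]  # singleton channel axis
    elif data.ndim != 5:
        raise ValueError(f"{path}: expected 3-, 4- or 5-D NIfTI, got {data.ndim}-D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: contains non-finite values")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size, img.affine


def read_mcc(
    real_path=None,
    imag_path=None,
    mag_path=None,
    phase_path=None,
    bval_path=None,
    bvec_path=None,
) -> MccImage:
    """Read a multi-channel complex image from a NIfTI pair.

    Give either ``real_path``/``imag_path`` or ``mag_path``/``phase_path``.
    4-D inputs get a singleton channel axis; the layout is
    ``(x, y, z, channel, volume)``.
    """
    if real_path is not None:
        re, voxel_size, _ = _load_5d(real_path)
        if imag_path is not None:
            im, _, _ = _load_5d(imag_path)
            if im.shape != re.shape:
                raise ValueError(f"shape mismatch: real {re.shape} vs imag {im.shape}")
            data = re + 1j * im
        else:
            data = re.astype(complex)
    elif mag_path is not None:
        mag, voxel_size, _ = _load_5d(mag_path)
        if phase_path is not None:
            ph, _, _ = _load_5d(phase_path)
            if ph.shape != mag.shape:
                raise ValueError(f"shape mismatch: magnitude {mag.shape} vs phase {ph.shape}")
            data = mag * np.exp(1j * ph)
        else:
            data = mag.astype(complex)
    else:
        raise ValueError("give real_path (+imag_path) or mag_path (+phase_path)")

    bvals = bvecs = None
    if bval_path is not None:
        bvals, bvecs = read_protocol(bval_path, bvec_path)
        if len(bvals) != data.shape[4]:
            raise ValueError(
                f".bval lists {len(bvals)} volumes but image has {data.shape[4]}"
            )
    return MccImage(data, voxel_size=voxel_size, bvals=bvals, bvecs=bvecs)


def write_nifti(data, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write an array as float32 NIfTI atomically (temp file + rename)."""
    data = np.asarray(data, dtype=np.float32)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    path = Path(path)
    fd, tmp = tempfile.mkstemp(suffix=".nii.gz", dir=path.parent)
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def write_mcc(image: MccImage, out_dir, prefix: str = "denoised") -> dict:
    """Write the complex data as a real/imaginary float32 NIfTI pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "real": out_dir / f"{prefix}_real.nii.gz",
        "imag": out_dir / f"{prefix}_imag.nii.gz",
    }
    write_nifti(image.data.real, paths["real"], image.voxel_size)
    write_nifti(image.data.imag, paths["imag"], image.voxel_size)
    return {k: str(v) for k, v in paths.items()}


def read_protocol(bval_path, bvec_path=None):
    """FSL-style b-value / gradient tables.

    b-vectors are normalized to unit length (zero vectors allowed at b=0;
    non-unit vectors are normalized with a warning).  Returns
    ``(bvals, bvecs)`` with bvecs shaped ``(V, 3)`` (or None without a
    ``.bvec`` file).
    """
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float).ravel())
    if bvec_path is None:
        return bvals, None
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError(
            f".bvec shape {bvecs.shape} incompatible with {len(bvals)} b-values"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = norms > 0
    off_unit = nonzero & ~np.isclose(norms, 1.0, atol=1e-3)
    if off_unit.any():
        warnings.warn(f"normalizing {int(off_unit.sum())} non-unit b-vectors", stacklevel=2)
    bvecs = bvecs.copy()
    bvecs[nonzero] /= norms[nonzero, None]
    return bvals, bvecs


def write_protocol(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.6f")


def shell_groups(bvals, width: float = 50.0) -> np.ndarray:
    """Group b-values into shells by rounding to the nearest ``width``."""
    return np.round(np.asarray(bvals, dtype=float) / width) * width


def write_outputs(results: dict, config: dict, out_dir, voxel_size=(1.0, 1.0, 1.0)) -> dict:
    """Write a dict of named arrays as NIfTI plus a JSON manifest.

    The manifest records the configuration, the package version and the
    produced filenames; filenames are deterministic functions of the keys.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, arr in results.items():
        arr = np.asarray(arr)
        if np.iscomplexobj(arr):
            for part, comp in (("real", arr.real), ("imag", arr.imag)):
                p = out_dir / f"{name}_{part}.nii.gz"
                write_nifti(comp, p, voxel_size)
                files[f"{name}_{part}"] = p.name
        else:
            p = out_dir / f"{name}.nii.gz"
            write_nifti(arr, p, voxel_size)
            files[name] = p.name
    manifest = {"config": config, "version": __version__, "files": files}
    manifest_path = out_dir / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    os.replace(tmp, manifest_path)
    return manifest
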