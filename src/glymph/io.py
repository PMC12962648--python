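"""NIfTI-1 and FSL bval/bvec readers/writers (nibabel-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from glymph.scheme import AcquisitionScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bval_bvec",
    "load_bval_bvec",
    "save_json",
    "load_json",
]


def _affine(voxel_size: float | tuple[float, float, float]) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


def save_nifti(
    path: str | Path,
    data: np.ndarray,
    voxel_size: float | tuple[float, float, float] = 1.0,
    dtype=np.float32,
) -> Path:
    """Write an array as NIfTI-1 with a diagonal (no-rotation) affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, voxel_size[3]) from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, voxel_size


def save_bval_bvec(
    base: str | Path, scheme: AcquisitionScheme
) -> tuple[Path, Path]:
    """Write `<base>.bval` / `<base>.bvec` in the FSL dialect.

    bval: one whitespace-separated row of b-values.  bvec: three rows,
    the x, y, z components of each direction.
    """
    base = Path(base)
    bval_path = base.with_suffix(".bval")
    bvec_path = base.with_suffix(".bvec")
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")
    return bval_path, bvec_path


def load_bval_bvec(
    bval_path: str | Path, bvec_path: str | Path, name: str = ""
) -> AcquisitionScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3) and bvals.shape[0] == 3:
        pass  # ambiguous 3x3; FSL convention is rows=components -> transpose
    return AcquisitionScheme(bvals, bvecs, name=name or str(bval_path))


def save_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
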