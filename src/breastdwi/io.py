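"""Standard-format I/O: FSL-dialect bval/bvec text, NIfTI volumes, provenance.

bval files are a single line of space-separated b-values; bvec files are
three lines (x, y, z components), one column per volume. Volumes go
through nibabel; maps inherit the input affine unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError

__all__ = [
    "read_bvals",
    "write_bvals",
    "read_bvecs",
    "write_bvecs",
    "load_volume",
    "save_volume",
    "write_provenance",
    "read_provenance",
]


def read_bvals(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"bval file not found: {path}")
    vals = np.atleast_1d(np.loadtxt(path, dtype=float))
    return vals.ravel()


def write_bvals(path, b_values) -> None:
    b = np.asarray(b_values, dtype=float)
    Path(path).write_text(" ".join(f"{v:g}" for v in b) + "\n")


def read_bvecs(path) -> np.ndarray:
    """Read a 3xN bvec file; returns an (N, 3) array of direction vectors."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"bvec file not found: {path}")
    arr = np.loadtxt(path, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 3:
        raise ValidationError(
            f"bvec file {path}: expected 3 rows (x, y, z), got shape {arr.shape}")
    return arr.T


def write_bvecs(path, directions) -> None:
    g = np.asarray(directions, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValidationError(f"directions: expected (N, 3), got {g.shape}")
    lines = [" ".join(f"{v:.8f}" for v in g[:, axis]) for axis in range(3)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_volume(path):
    """Load a NIfTI file -> (data array, affine)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_volume(path, data, affine=None) -> None:
    """Save an array as NIfTI, preserving the given affine (identity if None)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def write_provenance(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def read_provenance(path) -> dict:
    return json.loads(Path(path).read_text())
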