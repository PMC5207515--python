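"""NIfTI export/import of fields and masks (2D slices with grid geometry)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import Grid

__all__ = ["save_field", "load_field"]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = grid.h
    aff[1, 1] = grid.h
    return aff


def save_field(arr: np.ndarray, grid: Grid, path) -> Path:
    """Write a 2D field or boolean mask as a single-slice NIfTI volume."""
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} does not match grid {grid.shape}")
    data = arr.astype(np.uint8) if arr.dtype == bool else arr.astype(np.float64)
    img = nib.Nifti1Image(data[:, :, None], _affine(grid))
    img.header.set_zooms((grid.h, grid.h, 1.0))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_field(path) -> np.ndarray:
    """Read back a field written by :func:`save_field` (2D array)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj)[:, :, 0]
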