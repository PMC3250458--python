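"""NIfTI-1 reading and writing helpers (thin wrappers over nibabel)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["save_nifti", "load_nifti", "save_tensor_nifti", "load_tensor_nifti"]

# lower-triangular component order used for 6-channel tensor volumes
_LT = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine)), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_tensor_nifti(tensors: np.ndarray, affine: np.ndarray, path) -> None:
    """(x, y, z, 3, 3) symmetric tensors as a 6-component volume (Dxx, Dxy,
    Dyy, Dxz, Dyz, Dzz)."""
    comps = np.stack([tensors[..., i, j] for i, j in _LT], axis=-1)
    save_nifti(comps, affine, path)


def load_tensor_nifti(path):
    comps, affine = load_nifti(path)
    shape = comps.shape[:3]
    T = np.zeros(shape + (3, 3))
    for k, (i, j) in enumerate(_LT):
        T[..., i, j] = comps[..., k]
        T[..., j, i] = comps[..., k]
    return T, affine
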