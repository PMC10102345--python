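"""Reading and writing datasets: NIfTI-1 volumes with FSL bval/bvec tables.

A dataset stem ``<stem>`` maps to ``<stem>.nii.gz`` (4-D float32 signals),
``<stem>.bval`` (one whitespace-separated row) and ``<stem>.bvec`` (three
rows: x, y, z components; columns are volumes) — the layout FSL, DSI Studio
and most diffusion tools exchange.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWIDataset
from .scheme import AcquisitionScheme
from .tensor import TensorField

__all__ = [
    "write_dataset",
    "read_dataset",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "save_map",
    "save_tensor_field",
]


def write_bvals_bvecs(scheme: AcquisitionScheme, stem: str | Path) -> None:
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".bval"), scheme.b_values[None, :], fmt="%g")
    np.savetxt(stem.with_suffix(".bvec"), scheme.directions.T, fmt="%.8f")


def read_bvals_bvecs(stem: str | Path) -> AcquisitionScheme:
    stem = Path(stem)
    bval_path, bvec_path = stem.with_suffix(".bval"), stem.with_suffix(".bvec")
    bvals = np.atleast_2d(np.loadtxt(bval_path))
    if bvals.shape[0] != 1:
        raise ValueError(f"{bval_path}: expected a single row of b-values")
    bvals = bvals.ravel()
    if np.any(bvals < 0):
        raise ValueError(f"{bval_path}: negative b-value")
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] != 3:
        raise ValueError(
            f"{bvec_path}: expected 3 rows (x, y, z), found {bvecs.shape[0]}"
        )
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"{bvec_path}: {bvecs.shape[1]} columns but {bvals.size} b-values "
            f"in {bval_path}"
        )
    return AcquisitionScheme(bvals, bvecs.T)


def write_dataset(data: DWIDataset, stem: str | Path) -> None:
    """NIfTI-1 + bval/bvec; signals stored as float32, mask alongside."""
    stem = Path(stem)
    os.makedirs(stem.parent, exist_ok=True)
    img = nib.Nifti1Image(data.volumes.astype(np.float32), data.affine)
    nib.save(img, str(stem) + ".nii.gz")
    mask_img = nib.Nifti1Image(data.mask.astype(np.uint8), data.affine)
    nib.save(mask_img, str(stem) + "_mask.nii.gz")
    write_bvals_bvecs(data.scheme, stem)


def read_dataset(stem: str | Path) -> DWIDataset:
    stem = Path(stem)
    nii_path = Path(str(stem) + ".nii.gz")
    if not nii_path.exists():
        raise FileNotFoundError(nii_path)
    img = nib.load(str(nii_path))
    volumes = np.asarray(img.dataobj, dtype=np.float64)
    if volumes.ndim != 4:
        raise ValueError(f"{nii_path}: expected a 4-D volume")
    scheme = read_bvals_bvecs(stem)
    if volumes.shape[3] != scheme.volume_count:
        raise ValueError(
            f"{nii_path}: {volumes.shape[3]} volumes but gradient table lists "
            f"{scheme.volume_count}"
        )
    mask_path = Path(str(stem) + "_mask.nii.gz")
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    else:
        mask = np.ones(volumes.shape[:3], dtype=bool)
    return DWIDataset(
        volumes=volumes, scheme=scheme, mask=mask, affine=img.affine
    )


def save_map(array: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a scalar or RGB map (FA, MD, color FA) as NIfTI-1 float32."""
    nib.save(nib.Nifti1Image(array.astype(np.float32), affine), str(path))


def save_tensor_field(field: TensorField, path: str | Path) -> None:
    """Six-volume NIfTI in lower-triangular order Dxx, Dxy, Dyy, Dxz, Dyz, Dzz."""
    aff = np.diag([field.voxel_size_mm] * 3 + [1.0])
    save_map(field.to_lower_triangular(), aff, path)
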