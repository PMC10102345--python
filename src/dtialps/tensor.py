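"""Diffusion tensor fitting and scalar maps (FA, MD, color-coded FA).

The tensor model is fitted by linear least squares on log-signals,

    log S = log S0 − b · gᵀ D g,

solved jointly for the six unique tensor elements and log S0. Ordinary least
squares (OLS) is the default estimator; weighted least squares with weights
S² is available for noisy data. Shell selection restricts the fit to volumes
with b below a cutoff (default 1,150 s/mm²) so the monoexponential model
remains adequate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .scheme import AcquisitionScheme

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import DWIDataset

__all__ = [
    "TensorField",
    "TensorMetrics",
    "select_shells",
    "fit_tensor",
    "compute_metrics",
    "color_fa",
    "DEFAULT_B_MAX",
    "EIGENVALUE_FLOOR",
]

DEFAULT_B_MAX = 1150.0  # s/mm²; shells above this are dropped before fitting
EIGENVALUE_FLOOR = 1e-9  # mm²/s; clamp before FA/MD to avoid NaN in noise


@dataclass
class TensorField:
    """Per-voxel symmetric 3×3 diffusion tensors (mm²/s) on a regular grid."""

    tensors: np.ndarray  # (x, y, z, 3, 3)
    s0_map: np.ndarray
    mask: np.ndarray
    region_map: Optional[np.ndarray] = None
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (x, y, z, 3, 3)")
        asym = np.abs(self.tensors - np.swapaxes(self.tensors, -1, -2)).max()
        if asym > 1e-12:
            raise ValueError(f"tensors not symmetric (max asymmetry {asym:.2e})")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def diagonal(self, axis: int) -> np.ndarray:
        """Map of the diagonal element D_aa for axis a ∈ {0: x, 1: y, 2: z}."""
        return self.tensors[..., axis, axis]

    def to_lower_triangular(self) -> np.ndarray:
        """Six-volume representation in order Dxx, Dxy, Dyy, Dxz, Dyz, Dzz."""
        t = self.tensors
        return np.stack(
            [t[..., 0, 0], t[..., 0, 1], t[..., 1, 1],
             t[..., 0, 2], t[..., 1, 2], t[..., 2, 2]],
            axis=-1,
        )


@dataclass
class TensorMetrics:
    """Eigen-decomposition and rotation-invariant scalars of a tensor field."""

    eigenvalues: np.ndarray  # (x, y, z, 3), λ1 ≥ λ2 ≥ λ3
    eigenvectors: np.ndarray  # (x, y, z, 3, 3), columns match eigenvalues
    fa: np.ndarray
    md: np.ndarray
    mask: np.ndarray


def select_shells(data: "DWIDataset", b_max: float = DEFAULT_B_MAX) -> "DWIDataset":
    """Restrict a dataset to volumes with b ≤ ``b_max``, order preserved.

    Raises if the remainder cannot support a tensor fit (no b = 0 volume, or
    fewer than six distinct non-zero directions).
    """
    from .phantom import DWIDataset  # local import to avoid a cycle

    keep = data.scheme.b_values <= b_max
    sub = data.scheme.subset(keep)
    if not np.any(sub.b_values == 0):
        raise ValueError(f"no b=0 volume remains below b_max = {b_max:g}")
    weighted = sub.directions[sub.b_values > 0]
    n_dirs = np.unique(np.round(weighted, 6), axis=0).shape[0] if len(weighted) else 0
    if n_dirs < 6:
        raise ValueError(
            f"only {n_dirs} distinct non-zero directions remain below "
            f"b_max = {b_max:g}; at least 6 are required for a tensor fit"
        )
    return DWIDataset(
        volumes=data.volumes[..., keep],
        scheme=sub,
        mask=data.mask.copy(),
        affine=data.affine,
    )


def _design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Rows [1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]."""
    b = scheme.b_values
    gx, gy, gz = scheme.directions.T
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def fit_tensor(
    data: "DWIDataset",
    method: str = "ols",
    signal_floor: float = 1e-10,
) -> TensorField:
    """Least-squares tensor fit per voxel.

    Parameters
    ----------
    method : "ols" (default) or "wls" (weights = S², one reweighting pass).
    signal_floor : signals below this are floored before the log transform.

    Voxels outside the mask keep zero tensors and zero S0.
    """
    scheme = data.scheme
    if scheme.volume_count < 7:
        raise ValueError("tensor fit needs at least 7 volumes")
    design = _design_matrix(scheme)
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        cond = np.linalg.cond(design)
        raise ValueError(
            f"rank-deficient design (rank {rank} < 7, condition number "
            f"{cond:.3g}); encoding directions are coplanar or degenerate"
        )

    grid = data.grid_shape
    mask = data.mask.astype(bool)
    signals = np.maximum(data.volumes[mask], signal_floor)  # (nvox, nvol)
    logs = np.log(signals)

    if method == "ols":
        coef, *_ = np.linalg.lstsq(design, logs.T, rcond=None)
        coef = coef.T  # (nvox, 7)
    elif method == "wls":
        w = signals**2
        btwb = np.einsum("ni,vn,nj->vij", design, w, design)
        btwy = np.einsum("ni,vn,vn->vi", design, w, logs)
        coef = np.linalg.solve(btwb, btwy[..., None])[..., 0]
    else:
        raise ValueError(f"unknown method {method!r}; use 'ols' or 'wls'")

    tensors = np.zeros(grid + (3, 3))
    s0_map = np.zeros(grid)
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[:, i] for i in range(1, 7))
    flat = np.zeros((coef.shape[0], 3, 3))
    flat[:, 0, 0], flat[:, 1, 1], flat[:, 2, 2] = dxx, dyy, dzz
    flat[:, 0, 1] = flat[:, 1, 0] = dxy
    flat[:, 0, 2] = flat[:, 2, 0] = dxz
    flat[:, 1, 2] = flat[:, 2, 1] = dyz
    tensors[mask] = flat
    s0_map[mask] = np.exp(coef[:, 0])

    vox = data.affine[:3, :3]
    voxel_size = float(np.linalg.norm(vox[:, 0]))
    return TensorField(
        tensors=tensors, s0_map=s0_map, mask=mask, voxel_size_mm=voxel_size
    )


def compute_metrics(
    field: TensorField, eigenvalue_floor: float = EIGENVALUE_FLOOR
) -> TensorMetrics:
    """Eigenvalues/vectors, FA and MD per voxel.

    Negative eigenvalues (possible in noisy fits) are clamped to the floor
    before FA/MD; an all-zero tensor therefore yields FA = 0, not NaN.
    """
    vals, vecs = np.linalg.eigh(field.tensors)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    vals = np.maximum(vals, eigenvalue_floor)

    md = vals.mean(axis=-1)
    dev = vals - md[..., None]
    num = np.sqrt((dev**2).sum(axis=-1))
    den = np.sqrt((vals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)
    return TensorMetrics(
        eigenvalues=vals, eigenvectors=vecs, fa=fa, md=md, mask=field.mask.copy()
    )


def color_fa(metrics: TensorMetrics) -> np.ndarray:
    """Direction-encoded color map: (R, G, B) = FA · |principal eigenvector|.

    Red = left–right (x), green = anterior–posterior (y), blue =
    inferior–superior (z); each channel lies in [0, 1].
    """
    e1 = metrics.eigenvectors[..., :, 0]
    return np.clip(metrics.fa[..., None] * np.abs(e1), 0.0, 1.0)
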