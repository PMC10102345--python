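"""Parametric diffusion-MRI phantoms with periventricular fiber geometry.

The phantom mimics an axial slab at the level of the lateral-ventricle body:
projection fibers run along z (inferior–superior), association fibers along y
(anterior–posterior), and subcortical / callosal fibers along x (left–right),
mirrored across the midline. Perivascular fluid mobility is modelled by a
*glymphatic coefficient* g ≥ 0 that scales the x-axis diffusivity inside the
projection and association regions, independently per hemisphere — g = 1
leaves the fiber tensors at baseline, g > 1 boosts diffusion perpendicular to
both fiber populations, exactly the signal the ALPS index measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .scheme import AcquisitionScheme
from .tensor import TensorField

__all__ = [
    "REGION_LABELS",
    "PhantomSpec",
    "DWIDataset",
    "default_region_map",
    "build_phantom",
    "synthesize_signals",
    "add_rician_noise",
    "add_gaussian_noise",
]

# integer codes for the region map
REGION_LABELS = {
    "background": 0,
    "projection": 1,
    "association": 2,
    "subcortical": 3,
    "corpus_callosum": 4,
    "ventricle": 5,
    "lesion": 6,
}
_CODE_TO_NAME = {v: k for k, v in REGION_LABELS.items()}


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of a synthetic subject.

    Parameters
    ----------
    grid_shape : voxels along (x, y, z).
    voxel_size_mm : isotropic voxel edge, mm.
    baseline_eigenvalues : (λ1, λ2, λ3) fiber diffusivities, mm²/s, strictly
        positive and sorted descending.
    glymphatic_coefficient : (left, right) multipliers applied to the x-axis
        diffusivity (g · λ3) in projection and association regions.
    csf/background/lesion_diffusivity : isotropic diffusivities, mm²/s.
    noise_sigma : Rician noise scale in signal units (0 = noise-free).
    s0 : non-diffusion-weighted signal.
    lesion_center / lesion_size_vox : optional axis-aligned lesion box.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 10)
    voxel_size_mm: float = 2.0
    baseline_eigenvalues: tuple[float, float, float] = (1.4e-3, 0.4e-3, 0.4e-3)
    glymphatic_coefficient: tuple[float, float] = (1.0, 1.0)
    csf_diffusivity: float = 3.0e-3
    background_diffusivity: float = 0.8e-3
    lesion_diffusivity: float = 1.2e-3
    noise_sigma: float = 0.0
    s0: float = 1000.0
    seed: int = 0
    lesion_center: Optional[tuple[int, int, int]] = None
    lesion_size_vox: tuple[int, int, int] = (3, 3, 2)

    def __post_init__(self) -> None:
        l1, l2, l3 = self.baseline_eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(
                "baseline eigenvalues must be strictly positive and sorted "
                f"descending; got {self.baseline_eigenvalues}"
            )
        gl, gr = self.glymphatic_coefficient
        for hemi, g in (("left", gl), ("right", gr)):
            if g <= 0:
                raise ValueError(
                    f"glymphatic coefficient for {hemi} hemisphere must be > 0"
                )
            if g * l3 > l1:
                raise ValueError(
                    "glymphatic coefficient makes the x-axis diffusivity "
                    f"exceed λ1 in the projection/association regions "
                    f"({hemi} hemisphere): g·λ3 = {g * l3:.3g} > λ1 = {l1:.3g}"
                )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")

    @property
    def affine(self) -> np.ndarray:
        """RAS voxel-to-world transform (origin at voxel 0,0,0)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def with_coefficients(self, left: float, right: float) -> "PhantomSpec":
        return replace(self, glymphatic_coefficient=(left, right))


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal array with its acquisition scheme."""

    volumes: np.ndarray  # (x, y, z, volume)
    scheme: AcquisitionScheme
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, volume)")
        if self.volumes.shape[3] != self.scheme.volume_count:
            raise ValueError(
                f"{self.volumes.shape[3]} volumes but scheme lists "
                f"{self.scheme.volume_count}"
            )
        if np.any(self.volumes < 0):
            raise ValueError("signal values must be non-negative")
        if self.mask.shape != self.volumes.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]


def default_region_map(
    grid_shape: tuple[int, int, int] = (40, 40, 10),
    lesion_center: Optional[tuple[int, int, int]] = None,
    lesion_size_vox: tuple[int, int, int] = (3, 3, 2),
) -> np.ndarray:
    """Deterministic mirrored slab geometry at the ventricle-body level.

    From the midline outward (both hemispheres): ventricle, projection band,
    association band, subcortical band; corpus callosum sits medially,
    anterior and posterior to the ventricle. Bands span the full z extent so
    the axial ROI slice can sit anywhere.
    """
    nx, ny, nz = grid_shape
    if nx < 38 or ny < 20:
        raise ValueError("grid too small for the default geometry (min 38×20 in-plane)")
    region = np.zeros(grid_shape, dtype=np.int8)
    cx, cy = nx // 2, ny // 2
    yb = slice(cy - 6, cy + 6)  # central anterior–posterior band

    region[cx - 3 : cx + 3, yb, :] = REGION_LABELS["ventricle"]
    region[cx - 3 : cx + 3, cy - 10 : cy - 6, :] = REGION_LABELS["corpus_callosum"]
    region[cx - 3 : cx + 3, cy + 6 : cy + 10, :] = REGION_LABELS["corpus_callosum"]
    for lo, hi, label in (
        (3, 9, "projection"),
        (9, 15, "association"),
        (15, 19, "subcortical"),
    ):
        code = REGION_LABELS[label]
        region[cx - hi : cx - lo, yb, :] = code  # left hemisphere (low x)
        region[cx + lo : cx + hi, yb, :] = code  # right hemisphere
    if lesion_center is not None:
        sl = tuple(
            slice(max(0, c - s // 2), min(n, c - s // 2 + s))
            for c, s, n in zip(lesion_center, lesion_size_vox, grid_shape)
        )
        region[sl] = REGION_LABELS["lesion"]
    return region


def build_phantom(
    spec: PhantomSpec, region_map: Optional[np.ndarray] = None
) -> TensorField:
    """Assemble the ground-truth tensor field for a phantom subject.

    Every voxel carries a symmetric positive-definite tensor: projection
    fibers have their principal axis along z, association fibers along y,
    subcortical and callosal fibers along x; ventricle, lesion and
    background are isotropic. In the projection and association regions the
    Dxx element equals (hemispheric glymphatic coefficient) × λ3.
    """
    if region_map is None:
        region_map = default_region_map(
            spec.grid_shape, spec.lesion_center, spec.lesion_size_vox
        )
    if region_map.shape != spec.grid_shape:
        raise ValueError("region_map shape must equal spec.grid_shape")

    l1, l2, l3 = spec.baseline_eigenvalues
    nx = spec.grid_shape[0]
    left = np.zeros(spec.grid_shape, dtype=bool)
    left[: nx // 2] = True
    g = np.where(left, spec.glymphatic_coefficient[0], spec.glymphatic_coefficient[1])

    dxx = np.full(spec.grid_shape, spec.background_diffusivity)
    dyy = dxx.copy()
    dzz = dxx.copy()

    proj = region_map == REGION_LABELS["projection"]
    assoc = region_map == REGION_LABELS["association"]
    xfiber = (region_map == REGION_LABELS["subcortical"]) | (
        region_map == REGION_LABELS["corpus_callosum"]
    )
    # projection: z-principal; perivascular (x) diffusivity scaled by g
    dxx[proj], dyy[proj], dzz[proj] = (g * l3)[proj], l2, l1
    # association: y-principal
    dxx[assoc], dyy[assoc], dzz[assoc] = (g * l3)[assoc], l1, l2
    # subcortical / callosal: x-principal, unscaled
    dxx[xfiber], dyy[xfiber], dzz[xfiber] = l1, l2, l3
    for name, d in (
        ("ventricle", spec.csf_diffusivity),
        ("lesion", spec.lesion_diffusivity),
    ):
        m = region_map == REGION_LABELS[name]
        dxx[m] = dyy[m] = dzz[m] = d

    tensors = np.zeros(spec.grid_shape + (3, 3))
    tensors[..., 0, 0], tensors[..., 1, 1], tensors[..., 2, 2] = dxx, dyy, dzz

    eigmin = np.minimum(np.minimum(dxx, dyy), dzz)
    if np.any(eigmin <= 0):
        bad = np.unique(region_map[eigmin <= 0])
        names = ", ".join(_CODE_TO_NAME[int(c)] for c in bad)
        raise ValueError(f"non-positive-definite tensors in region(s): {names}")

    return TensorField(
        tensors=tensors,
        s0_map=np.full(spec.grid_shape, spec.s0),
        mask=np.ones(spec.grid_shape, dtype=bool),
        region_map=region_map,
        voxel_size_mm=spec.voxel_size_mm,
    )


def synthesize_signals(
    field: TensorField,
    scheme: AcquisitionScheme,
    s0: Optional[float] = None,
    affine: Optional[np.ndarray] = None,
) -> DWIDataset:
    """Noise-free signals under the monoexponential tensor model.

    S(b, g) = S0 · exp(−b · gᵀ D g) per voxel and volume; b = 0 volumes equal
    S0 exactly.
    """
    if np.any(scheme.b_values < 0):
        raise ValueError("negative b-value in scheme")
    quad = np.einsum(
        "ni,...ij,nj->...n", scheme.directions, field.tensors, scheme.directions
    )
    if np.any(quad < -1e-15):
        raise ValueError("tensor field is not positive semidefinite")
    s0_map = field.s0_map if s0 is None else np.full(field.grid_shape, float(s0))
    signals = s0_map[..., None] * np.exp(-scheme.b_values * np.clip(quad, 0, None))
    if affine is None:
        affine = np.diag([field.voxel_size_mm] * 3 + [1.0])
    return DWIDataset(
        volumes=signals, scheme=scheme, mask=field.mask.copy(), affine=affine
    )


def add_rician_noise(data: DWIDataset, sigma: float, seed: int) -> DWIDataset:
    """Magnitude-MRI (Rician) noise: sqrt((S+n₁)² + n₂²), n ~ N(0, σ²).

    Deterministic for a fixed seed; sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return data
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=data.volumes.shape)
    n2 = rng.normal(0.0, sigma, size=data.volumes.shape)
    noisy = np.sqrt((data.volumes + n1) ** 2 + n2**2)
    return DWIDataset(
        volumes=noisy, scheme=data.scheme, mask=data.mask.copy(), affine=data.affine
    )


def add_gaussian_noise(data: DWIDataset, sigma: float, seed: int) -> DWIDataset:
    """Additive Gaussian alternative (clipped at zero to keep magnitudes valid)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return data
    rng = np.random.default_rng(seed)
    noisy = np.clip(data.volumes + rng.normal(0.0, sigma, data.volumes.shape), 0, None)
    return DWIDataset(
        volumes=noisy, scheme=data.scheme, mask=data.mask.copy(), affine=data.affine
    )
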