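"""ROI placement, axis-wise diffusivity extraction, and the ALPS index.

At the level of the lateral-ventricle body, perivascular spaces run along
the x-axis (left–right), perpendicular to both the projection fibers (z) and
the association fibers (y). The ALPS index contrasts diffusivity along the
perivascular direction with diffusivity along the fibers' own axes:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where D_aa is the mean diagonal tensor element over the ROI. An index near 1
means no preferential perivascular diffusion; larger values indicate greater
water mobility along the perivascular channel. "Diffusivity along axis a" is
the diagonal tensor element eᵃᵀ D eᵃ in the image frame, not an eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tensor import TensorField, TensorMetrics

__all__ = [
    "RoiDefinition",
    "RoiSet",
    "AlpsResult",
    "place_rois",
    "auto_roi_definitions",
    "roi_definitions_from_yaml",
    "extract_axis_diffusivities",
    "compute_alps",
    "extract_roi_metrics",
    "alps_for_hemisphere",
]

# physical ROI extents (mm) along (x, y, z)
ALPS_ROI_SIZE_MM = (12.0, 4.0, 2.0)
TRACT_ROI_SIZE_MM = (4.0, 4.0, 2.0)  # CST and corpus callosum


@dataclass(frozen=True)
class RoiDefinition:
    """An axis-aligned cuboid ROI: center voxel, physical size, labels."""

    name: str  # "projection" | "association" | "cst" | "corpus_callosum"
    hemisphere: str  # "left" | "right"
    center_vox: tuple[int, int, int]
    size_mm: tuple[float, float, float]


@dataclass
class RoiSet:
    """Placed ROIs as voxel index tuples, plus the lesion-exclusion verdict."""

    rois: dict[tuple[str, str], tuple[np.ndarray, ...]]  # (name, hemi) -> ix
    voxel_size_mm: float
    slice_level: int
    excluded: bool = False
    overlap_rois: list[str] = field(default_factory=list)

    def voxels(self, name: str, hemisphere: str) -> tuple[np.ndarray, ...]:
        return self.rois[(name, hemisphere)]

    def n_voxels(self, name: str, hemisphere: str) -> int:
        return len(self.rois[(name, hemisphere)][0])


@dataclass(frozen=True)
class AlpsResult:
    """Axis diffusivities (mm²/s) and the ALPS index for one hemisphere."""

    hemisphere: str
    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float

    @property
    def index(self) -> float:
        return compute_alps(
            self.dxx_proj, self.dxx_assoc, self.dyy_proj, self.dzz_assoc
        )

    def to_row(self, subject_id: str, excluded: bool = False) -> dict:
        return {
            "subject_id": subject_id,
            "hemisphere": self.hemisphere,
            "dxx_proj": self.dxx_proj,
            "dxx_assoc": self.dxx_assoc,
            "dyy_proj": self.dyy_proj,
            "dzz_assoc": self.dzz_assoc,
            "alps_index": self.index,
            "excluded_flag": excluded,
        }


def _roi_slices(
    center: tuple[int, int, int],
    size_mm: tuple[float, float, float],
    voxel_size: float,
    grid_shape: tuple[int, int, int],
    name: str,
) -> tuple[slice, slice, slice]:
    slices = []
    for c, s_mm, n in zip(center, size_mm, grid_shape):
        extent = max(1, int(round(s_mm / voxel_size)))
        start = int(c) - extent // 2
        stop = start + extent
        if start < 0 or stop > n:
            raise ValueError(
                f"ROI {name!r} (center {center}, size {size_mm} mm) extends "
                f"outside the grid {grid_shape}"
            )
        slices.append(slice(start, stop))
    return tuple(slices)


def place_rois(
    definitions: list[RoiDefinition],
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    lesion_mask: Optional[np.ndarray] = None,
    slice_level: Optional[int] = None,
) -> RoiSet:
    """Realize ROI definitions as voxel sets and apply the lesion rule.

    A 12×4×2 mm ROI at 2 mm isotropic voxels contains exactly 6×2×1 = 12
    voxels. If any ROI overlaps the lesion mask the subject is flagged
    excluded — the ROI is never trimmed or nudged.
    """
    rois: dict[tuple[str, str], tuple[np.ndarray, ...]] = {}
    overlap: list[str] = []
    for d in definitions:
        sl = _roi_slices(d.center_vox, d.size_mm, voxel_size_mm, grid_shape, d.name)
        grid = np.zeros(grid_shape, dtype=bool)
        grid[sl] = True
        idx = np.nonzero(grid)
        if idx[0].size == 0:
            raise ValueError(f"ROI {d.name!r} is empty")
        rois[(d.name, d.hemisphere)] = idx
        if lesion_mask is not None and np.any(lesion_mask[sl]):
            overlap.append(f"{d.hemisphere}_{d.name}")
    level = slice_level if slice_level is not None else definitions[0].center_vox[2]
    return RoiSet(
        rois=rois,
        voxel_size_mm=voxel_size_mm,
        slice_level=level,
        excluded=bool(overlap),
        overlap_rois=overlap,
    )


def auto_roi_definitions(
    field: TensorField, slice_level: Optional[int] = None
) -> list[RoiDefinition]:
    """Seed ROI centers from the phantom's region labels.

    For each hemisphere: ALPS ROIs centered in the projection and association
    bands, a CST ROI inside the projection band (the corticospinal tract is a
    projection pathway), and a callosal ROI in the corpus-callosum block of
    that hemisphere's half. Requires a region map.
    """
    from .phantom import REGION_LABELS  # local import avoids a cycle

    if field.region_map is None:
        raise ValueError("auto ROI placement needs a region map")
    region = field.region_map
    nx, _, nz = region.shape
    z = nz // 2 if slice_level is None else int(slice_level)
    half = {"left": slice(0, nx // 2), "right": slice(nx // 2, nx)}

    defs: list[RoiDefinition] = []
    for hemi, xs in half.items():
        for name, size in (
            ("projection", ALPS_ROI_SIZE_MM),
            ("association", ALPS_ROI_SIZE_MM),
            ("cst", TRACT_ROI_SIZE_MM),
            ("corpus_callosum", TRACT_ROI_SIZE_MM),
        ):
            label = "projection" if name == "cst" else name
            sub = region[xs, :, z] == REGION_LABELS[label]
            if not sub.any():
                raise ValueError(
                    f"region {label!r} absent in {hemi} hemisphere at slice {z}"
                )
            ix, iy = np.nonzero(sub)
            if name == "corpus_callosum":
                # label has anterior and posterior blocks; seed the anterior one
                anterior = iy < region.shape[1] // 2
                ix, iy = ix[anterior], iy[anterior]
            # bounds midpoint keeps even-extent ROIs inside the band exactly
            cx = (int(ix.min()) + int(ix.max()) + 1) // 2 + half[hemi].start
            cy = (int(iy.min()) + int(iy.max()) + 1) // 2
            if name == "cst":  # offset within the band so CST ≠ ALPS ROI center
                cy -= 3
            defs.append(
                RoiDefinition(
                    name=name, hemisphere=hemi, center_vox=(cx, cy, z), size_mm=size
                )
            )
    return defs


def roi_definitions_from_yaml(path) -> list[RoiDefinition]:
    """ROI definitions from a YAML list of {name, hemisphere, center, size_mm}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for item in raw:
        defs.append(
            RoiDefinition(
                name=str(item["name"]),
                hemisphere=str(item["hemisphere"]),
                center_vox=tuple(int(v) for v in item["center"]),
                size_mm=tuple(float(v) for v in item["size_mm"]),
            )
        )
    if not defs:
        raise ValueError(f"{path}: no ROI definitions found")
    return defs


def extract_axis_diffusivities(
    field: TensorField, rois: RoiSet, hemisphere: str
) -> AlpsResult:
    """Mean diagonal tensor elements over the projection/association ROIs."""
    proj = rois.voxels("projection", hemisphere)
    assoc = rois.voxels("association", hemisphere)
    if proj[0].size == 0 or assoc[0].size == 0:
        raise ValueError(f"empty ALPS ROI in {hemisphere} hemisphere")
    return AlpsResult(
        hemisphere=hemisphere,
        dxx_proj=float(field.diagonal(0)[proj].mean()),
        dxx_assoc=float(field.diagonal(0)[assoc].mean()),
        dyy_proj=float(field.diagonal(1)[proj].mean()),
        dzz_assoc=float(field.diagonal(2)[assoc].mean()),
    )


def compute_alps(
    dxx_proj: float, dxx_assoc: float, dyy_proj: float, dzz_assoc: float
) -> float:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    for name, v in (
        ("dxx_proj", dxx_proj),
        ("dxx_assoc", dxx_assoc),
        ("dyy_proj", dyy_proj),
        ("dzz_assoc", dzz_assoc),
    ):
        if v < 0:
            raise ValueError(f"negative diffusivity {name} = {v:g}")
    denom = 0.5 * (dyy_proj + dzz_assoc)
    if denom <= 0:
        raise ValueError(
            "ALPS denominator mean(Dyy_proj, Dzz_assoc) is zero — fiber-axis "
            "diffusivities vanish; check ROI placement and fit"
        )
    return 0.5 * (dxx_proj + dxx_assoc) / denom


def alps_for_hemisphere(
    field: TensorField, rois: RoiSet, hemisphere: str
) -> AlpsResult:
    """Convenience: extract diffusivities and package the index."""
    return extract_axis_diffusivities(field, rois, hemisphere)


def extract_roi_metrics(metrics: TensorMetrics, rois: RoiSet) -> pd.DataFrame:
    """Mean FA and MD over every placed CST / corpus-callosum ROI.

    Returns a tidy frame with columns roi, hemisphere, fa, md, n_voxels.
    """
    rows = []
    for (name, hemi), idx in rois.rois.items():
        if name not in ("cst", "corpus_callosum"):
            continue
        if idx[0].size == 0:
            raise ValueError(f"empty ROI {name!r} ({hemi})")
        rows.append(
            {
                "roi": name,
                "hemisphere": hemi,
                "fa": float(metrics.fa[idx].mean()),
                "md": float(metrics.md[idx].mean()),
                "n_voxels": int(idx[0].size),
            }
        )
    return pd.DataFrame(rows)
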