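"""Reference-tissue VOIs and their uptake statistics.

Two VOI families are supported, matching clinical practice for liver and
bone marrow reference regions:

* spheres of 29 / 41 / 48 mm diameter placed in the liver (the 29 mm
  sphere is the default, being closest to the PERCIST convention);
* vertebral bodies (T12 by default; L3 or the union T10-T11-T12 as
  alternatives) delineated on CT by a Hounsfield-unit range inside a
  search box, reduced to the largest connected component with holes
  filled.

Sphere membership is decided by the voxel center: a voxel belongs to the
sphere iff its center lies within diameter/2 of the sphere center. This
is the simplest rule that makes masks, and hence thresholds, bit-stable
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import GridGeometry, VolumePair
from .reference import ReferenceMeasure

LIVER_SPHERE_PRESETS = {"sphere29": 29.0, "sphere41": 41.0, "sphere48": 48.0}
MARROW_PRESETS = {
    "T12": ("T12",),
    "L3": ("L3",),
    "T10T11T12": ("T10", "T11", "T12"),
}
DEFAULT_HU_RANGE = (150.0, 1500.0)

__all__ = [
    "LIVER_SPHERE_PRESETS",
    "MARROW_PRESETS",
    "DEFAULT_HU_RANGE",
    "VoiStats",
    "VoiPlacements",
    "sphere_mask",
    "delineate_vertebra",
    "voi_stats",
    "reference_measure",
]


class PlacementError(ValueError):
    """A VOI could not be placed on the grid."""


class DelineationError(ValueError):
    """HU-based delineation produced an empty region."""


@dataclass(frozen=True)
class VoiStats:
    """Voxel statistics of the PET signal inside one VOI.

    ``sd_suv`` is the population SD (divisor N) by default: the VOI is
    the complete set of voxels measured, and the thresholding criteria
    use the SD as a spread scale rather than as an estimator of a
    sampling distribution.
    """

    mean_suv: float
    sd_suv: float
    min_suv: float
    max_suv: float
    voxel_count: int
    volume_ml: float


@dataclass(frozen=True)
class VoiPlacements:
    """Where to put the reference VOIs on a given scan.

    ``liver_center_mm``: world coordinates of the liver sphere center.
    ``vertebra_boxes``: per vertebra name, index ranges
    ``((x0, x1), (y0, y1), (z0, z1))`` (half-open) bounding the HU search.
    """

    liver_center_mm: tuple[float, float, float]
    vertebra_boxes: dict[str, tuple[tuple[int, int], ...]]
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE


def sphere_mask(
    center_mm: tuple[float, float, float], diameter_mm: float, grid: GridGeometry
) -> np.ndarray:
    """Binary mask of voxels whose centers lie inside the sphere."""
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter_mm}")
    radius = diameter_mm / 2.0
    d2 = np.zeros(grid.shape, dtype=np.float64)
    for ax in range(3):
        delta = grid.voxel_centers(ax) - center_mm[ax]
        shape = [1, 1, 1]
        shape[ax] = -1
        d2 = d2 + (delta**2).reshape(shape)
    mask = d2 <= radius**2
    if not mask.any():
        raise PlacementError(
            f"sphere (d={diameter_mm} mm) at {center_mm} contains no voxel center"
        )
    return mask


def delineate_vertebra(
    ct: np.ndarray,
    search_box: tuple[tuple[int, int], ...],
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE,
) -> np.ndarray:
    """Delineate a vertebral body on CT by Hounsfield units.

    Voxels inside ``search_box`` with HU in ``hu_range`` are kept,
    reduced to the largest 26-connected component, and interior holes
    are filled. Returned on the CT grid (caller resamples to PET).
    """
    lo, hi = hu_range
    if not lo < hi:
        raise ValueError(f"empty HU range {hu_range}")
    (x0, x1), (y0, y1), (z0, z1) = search_box
    if not (
        0 <= x0 < x1 <= ct.shape[0]
        and 0 <= y0 < y1 <= ct.shape[1]
        and 0 <= z0 < z1 <= ct.shape[2]
    ):
        raise ValueError(f"search box {search_box} outside grid {ct.shape}")
    sub = ct[x0:x1, y0:y1, z0:z1]
    hit = (sub >= lo) & (sub <= hi)
    if not hit.any():
        raise DelineationError(
            f"no voxels in HU range {hu_range} inside box {search_box}"
        )
    labels, n = ndimage.label(hit, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = labels == (int(np.argmax(sizes)) + 1)
    keep = ndimage.binary_fill_holes(keep)
    mask = np.zeros(ct.shape, dtype=bool)
    mask[x0:x1, y0:y1, z0:z1] = keep
    return mask


def voi_stats(pet: np.ndarray, mask: np.ndarray, grid: GridGeometry, ddof: int = 0) -> VoiStats:
    """Mean / SD / min / max of the PET signal over a binary mask."""
    m = np.asarray(mask, dtype=bool)
    if m.shape != pet.shape:
        raise ValueError(f"mask shape {m.shape} does not match PET {pet.shape}")
    vals = np.asarray(pet, dtype=np.float64)[m]
    if vals.size == 0:
        raise ValueError("empty mask")
    return VoiStats(
        mean_suv=float(vals.mean()),
        sd_suv=float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0,
        min_suv=float(vals.min()),
        max_suv=float(vals.max()),
        voxel_count=int(vals.size),
        volume_ml=float(vals.size) * grid.voxel_volume_ml,
    )


def marrow_mask(
    pair: VolumePair, placements: VoiPlacements, choice: str = "T12"
) -> np.ndarray:
    """Union of HU-delineated vertebra masks for a marrow VOI preset."""
    if choice not in MARROW_PRESETS:
        raise ValueError(f"unknown marrow VOI choice {choice!r}")
    mask = np.zeros(pair.ct.shape, dtype=bool)
    for name in MARROW_PRESETS[choice]:
        if name not in placements.vertebra_boxes:
            raise PlacementError(f"no search box given for vertebra {name}")
        mask |= delineate_vertebra(
            pair.ct, placements.vertebra_boxes[name], placements.hu_range
        )
    return mask


def reference_measure(
    pair: VolumePair,
    tissue: str,
    placements: VoiPlacements,
    voi_choice: str | None = None,
    ddof: int = 0,
) -> ReferenceMeasure:
    """Measure a reference tissue's uptake on one scan.

    Defaults: the 29 mm liver sphere and the T12 vertebra.
    """
    if tissue == "liver":
        choice = voi_choice or "sphere29"
        if choice not in LIVER_SPHERE_PRESETS:
            raise ValueError(f"unknown liver VOI choice {choice!r}")
        mask = sphere_mask(
            placements.liver_center_mm, LIVER_SPHERE_PRESETS[choice], pair.grid
        )
    elif tissue == "marrow":
        mask = marrow_mask(pair, placements, voi_choice or "T12")
    else:
        raise ValueError(f"tissue must be 'liver' or 'marrow', got {tissue!r}")
    stats = voi_stats(pair.pet, mask, pair.grid, ddof=ddof)
    return ReferenceMeasure(
        patient_id=pair.patient_id,
        stage=pair.stage,
        tissue=tissue,
        mean_suv=stats.mean_suv,
        sd_suv=stats.sd_suv,
    )
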