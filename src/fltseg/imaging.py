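"""Volume containers, SUV conversion, NIfTI I/O and grid resampling.

All grids in this package are axis-aligned: world coordinates are
``origin + index * spacing`` with strictly positive spacing. Oblique
affines are rejected at load time rather than silently reoriented.

Decay correction contract: activity concentrations are assumed to be
decay-corrected by the scanner at reconstruction time; :func:`to_suv`
neither applies nor removes decay correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

STAGES = ("baseline", "iPET", "fPET")

__all__ = [
    "STAGES",
    "GridGeometry",
    "ScanMeta",
    "VolumePair",
    "to_suv",
    "load_volume",
    "save_volume",
    "load_pair",
    "save_pair",
    "resample_to_grid",
    "resample_mask_to_pet",
]


class FormatError(ValueError):
    """Raised for malformed or incompatible on-disk volumes."""


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts along (x, y, z).
    spacing : tuple of float
        Voxel edge lengths in mm, strictly positive.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def same_grid(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan acquisition metadata used for SUV normalization.

    ``injected_activity`` is the decay-corrected injected activity in MBq;
    ``body_weight`` in kg. Administered activity outside the protocol band
    of 1.8-2.6 MBq/kg triggers a warning, not an error.
    """

    body_weight: float
    injected_activity: float
    injection_to_scan_minutes: float = 60.0

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if self.injected_activity <= 0:
            raise ValueError(
                f"injected_activity must be > 0, got {self.injected_activity}"
            )

    @property
    def activity_per_kg(self) -> float:
        return self.injected_activity / self.body_weight

    def check_protocol_band(self, low: float = 1.8, high: float = 2.6) -> Optional[str]:
        """Return a warning string if MBq/kg falls outside [low, high]."""
        apk = self.activity_per_kg
        if not (low <= apk <= high):
            return (
                f"administered activity {apk:.2f} MBq/kg outside the "
                f"protocol band [{low}, {high}]"
            )
        return None


@dataclass
class VolumePair:
    """Co-registered CT (HU) and PET (SUV) volumes on one shared grid."""

    ct: np.ndarray
    pet: np.ndarray
    grid: GridGeometry
    patient_id: str
    stage: str

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=np.float32)
        self.pet = np.asarray(self.pet, dtype=np.float32)
        if self.ct.shape != tuple(self.grid.shape):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match grid {self.grid.shape}"
            )
        if self.pet.shape != tuple(self.grid.shape):
            raise ValueError(
                f"pet shape {self.pet.shape} does not match grid {self.grid.shape}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not np.all(np.isfinite(self.ct)) or not np.all(np.isfinite(self.pet)):
            raise ValueError("non-finite voxels in CT or PET volume")

    @property
    def voxel_spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing


def to_suv(concentration: np.ndarray, meta: ScanMeta) -> np.ndarray:
    """Convert an activity-concentration grid (kBq/ml) to body-weight SUV.

    SUV = C [kBq/ml] * weight [kg] / activity [MBq]. The kBq/MBq and
    kg/ml unit factors cancel (1 MBq = 1000 kBq, 1 kg of water = 1000 ml),
    so the formula is dimensionally a pure ratio.
    """
    conc = np.asarray(concentration, dtype=np.float64)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be non-negative")
    return conc * (meta.body_weight / meta.injected_activity)


def _geometry_from_nifti(img: nib.Nifti1Image, path: str | Path) -> GridGeometry:
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0.0, atol=1e-4):
        raise FormatError(
            f"{path}: oblique affine not supported (axis-aligned grids only)"
        )
    diag = np.diag(aff[:3, :3])
    if np.any(diag <= 0):
        raise FormatError(f"{path}: non-positive voxel spacing in affine")
    shape = tuple(int(n) for n in img.shape[:3])
    return GridGeometry(shape, tuple(float(d) for d in diag), tuple(float(o) for o in aff[:3, 3]))


def load_volume(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Load a NIfTI volume as (data, geometry); rejects oblique affines."""
    img = nib.load(str(path))
    geom = _geometry_from_nifti(img, path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got shape {data.shape}")
    return data, geom


def save_volume(data: np.ndarray, grid: GridGeometry, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine())
    nib.save(img, str(path))


def resample_to_grid(
    data: np.ndarray,
    src: GridGeometry,
    dst: GridGeometry,
    order: int = 1,
    fill: float = 0.0,
) -> np.ndarray:
    """Resample ``data`` from grid ``src`` onto grid ``dst``.

    ``order=1`` (trilinear) for intensity volumes, ``order=0``
    (nearest-neighbour) for label masks. Output voxel centers falling
    outside the source grid get ``fill``.
    """
    if src.same_grid(dst):
        return np.array(data, copy=True)
    coords = np.meshgrid(
        *[
            (dst.voxel_centers(ax) - src.origin[ax]) / src.spacing[ax]
            for ax in range(3)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64),
        np.stack(coords),
        order=order,
        mode="constant",
        cval=fill,
    )


def load_pair(
    ct_path: str | Path,
    pet_path: str | Path,
    patient_id: str,
    stage: str,
    meta: ScanMeta | None = None,
    pet_is_concentration: bool = False,
) -> VolumePair:
    """Load a CT/PET pair; CT is resampled (trilinear) onto the PET grid.

    When ``pet_is_concentration`` the PET file holds kBq/ml and ``meta``
    must be given for SUV conversion.
    """
    ct, ct_geom = load_volume(ct_path)
    pet, pet_geom = load_volume(pet_path)
    if not np.all(np.isfinite(ct)) or not np.all(np.isfinite(pet)):
        raise ValueError("non-finite voxels in loaded volumes")
    if pet_is_concentration:
        if meta is None:
            raise ValueError("meta is required to convert concentration to SUV")
        pet = to_suv(pet, meta)
    if not ct_geom.same_grid(pet_geom):
        ct = resample_to_grid(ct, ct_geom, pet_geom, order=1, fill=-1000.0)
    return VolumePair(ct=ct, pet=pet, grid=pet_geom, patient_id=patient_id, stage=stage)


def save_pair(pair: VolumePair, ct_path: str | Path, pet_path: str | Path) -> None:
    save_volume(pair.ct, pair.grid, ct_path)
    save_volume(pair.pet, pair.grid, pet_path)


def resample_mask_to_pet(
    mask: np.ndarray, mask_grid: GridGeometry, pet_grid: GridGeometry
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto the PET grid."""
    m = np.asarray(mask)
    if not np.isin(m, [0, 1]).all() and m.dtype != bool:
        raise ValueError("mask must be binary")
    out = resample_to_grid(m.astype(np.float64), mask_grid, pet_grid, order=0)
    return out > 0.5
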