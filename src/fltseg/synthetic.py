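"""Synthetic PET/CT phantom cohorts with known ground truth.

Every downstream stage of the pipeline (VOI statistics, normal ranges,
threshold estimation, segmentation) is testable without clinical data by
generating digital phantoms that carry the statistical structure the
analysis assumes:

* inter-patient reference uptake drawn from Gaussians truncated at
  0.5 SUV — liver 5.1 +/- 1.4, bone marrow 7.8 +/- 2.7 by default, the
  typical normal ranges for this tracer;
* a CT with an air border (-1000 HU), soft-tissue body (40 HU) and
  vertebral bodies T10/T11/T12/L3 at trabecular-bone HU (300), so the
  HU-based vertebra delineation is exercised for real;
* a PET with liver and marrow plateaus at each patient's true uptake,
  multiplicative voxel noise of a configurable coefficient of variation,
  one physiological hot sphere (a bladder-like region that must be
  excluded from segmentation), and ellipsoidal lesions whose *minimum*
  SUV is a controlled fraction of the patient's reference uptake.

Lesion uptake falls linearly from a central plateau to the designed
minimum at the rim. After rasterization the profile is affinely rescaled
so the noiseless voxel minimum equals the designed minimum exactly, and
noisy lesion voxels are floored at that minimum; this keeps the realized
SUVmin tightly controlled (the quantity the threshold estimator
averages) even under voxel noise.

The phantom body occupies a fixed 160 x 160 x 200 mm layout; grids too
small to hold the 48 mm liver sphere and the spine stack are rejected
with an error naming the offending structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import json

import numpy as np
import pandas as pd

from .imaging import STAGES, GridGeometry, VolumePair, save_volume
from .reference import ReferenceMeasure
from .thresholds import LesionRecord
from .voi import VoiPlacements

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_summary_cohort",
    "write_cohort",
]

# fixed phantom layout, in mm (world coordinates, origin at 0)
_BODY_EXTENT = (160.0, 160.0, 200.0)
_AIR_BORDER_MM = 5.0
_LIVER_BOX = ((10.0, 80.0), (10.0, 80.0), (112.5, 190.0))
_LIVER_SPHERE_CENTER = (45.0, 45.0, 150.0)
_VERTEBRA_XY = ((105.0, 135.0), (105.0, 135.0))
_VERTEBRA_Z = {  # 22 mm tall bodies, 6 mm disc gaps, cranial to caudal
    "T10": (147.0, 169.0),
    "T11": (119.0, 141.0),
    "T12": (91.0, 113.0),
    "L3": (63.0, 85.0),
}
_PHYSIO_CENTER = (120.0, 45.0, 150.0)
_PHYSIO_RADIUS = 12.0
_LESION_ZONE = ((15.0, 145.0), (15.0, 145.0), (12.0, 55.0))
_LESION_CELLS = (3, 3, 1)  # disjoint placement cells inside the zone
_LESION_MARGIN = 2.0  # mm clearance inside a cell
_MIN_SEMI_AXIS = 4.0  # mm


class SizingError(ValueError):
    """The requested grid cannot hold a required phantom structure."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic phantom cohort.

    ``lesion_count_per_stage`` and ``lesion_min_fraction`` accept either
    a scalar (applied to every stage) or a per-stage mapping. The default
    minimum-SUV fractions decrease along treatment (0.50 / 0.35 / 0.27),
    mirroring the decreasing tendency of relative thresholds across
    stages. ``lesion_reference`` names the tissue whose true uptake the
    planted lesion minima are scaled against.
    """

    n_patients: int = 16
    stages: tuple[str, ...] = STAGES
    liver_mean: float = 5.1
    liver_sd: float = 1.4
    marrow_mean: float = 7.8
    marrow_sd: float = 2.7
    within_voi_cv: float = 0.05
    lesion_count_per_stage: Mapping[str, int] | int = field(
        default_factory=lambda: {"baseline": 3, "iPET": 2, "fPET": 1}
    )
    lesion_min_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"baseline": 0.50, "iPET": 0.35, "fPET": 0.27}
    )
    lesion_reference: str = "liver"
    lesion_peak_ratio: float = 2.0
    background_suv: float = 1.0
    physiological_suv: float = 12.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 300.0
    air_hu: float = -1000.0
    stage_drift: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STAGES}
    )
    truncate_suv: float = 0.5
    voxel_spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    grid_shape: tuple[int, int, int] = (64, 64, 80)
    seed: int = 0

    def lesion_count(self, stage: str) -> int:
        if isinstance(self.lesion_count_per_stage, Mapping):
            return int(self.lesion_count_per_stage.get(stage, 0))
        return int(self.lesion_count_per_stage)

    def min_fraction(self, stage: str) -> float:
        if isinstance(self.lesion_min_fraction, Mapping):
            return float(self.lesion_min_fraction[stage])
        return float(self.lesion_min_fraction)

    def grid(self) -> GridGeometry:
        return GridGeometry(self.grid_shape, self.voxel_spacing)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(s not in STAGES for s in self.stages):
            raise ValueError(f"stages must be drawn from {STAGES}")
        for name, sd in (("liver_sd", self.liver_sd), ("marrow_sd", self.marrow_sd)):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.within_voi_cv < 0:
            raise ValueError("within_voi_cv must be >= 0")
        if self.lesion_reference not in ("liver", "marrow"):
            raise ValueError("lesion_reference must be 'liver' or 'marrow'")
        if self.lesion_peak_ratio < 1.0:
            raise ValueError("lesion_peak_ratio must be >= 1")
        for stage in self.stages:
            if self.min_fraction(stage) <= 0:
                raise ValueError("lesion_min_fraction must be > 0")
            max_lesions = int(np.prod(_LESION_CELLS))
            if not 0 <= self.lesion_count(stage) <= max_lesions:
                raise SizingError(
                    f"lesion count at {stage} exceeds the {max_lesions} "
                    "disjoint placement cells of the lesion zone"
                )
        extent = tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))
        names = ("48 mm liver sphere (x)", "spine region (y)", "spine stack (z)")
        for ax, (ext, req, name) in enumerate(zip(extent, _BODY_EXTENT, names)):
            if ext < req - 1e-9:
                raise SizingError(
                    f"grid extent {ext:.0f} mm on axis {ax} cannot hold the "
                    f"{name}: need >= {req:.0f} mm"
                )


@dataclass
class GroundTruth:
    """Planted truth for one patient-stage phantom scan."""

    patient_id: str
    stage: str
    liver_mask: np.ndarray
    vertebra_masks: dict[str, np.ndarray]
    lesion_masks: dict[str, np.ndarray]
    physiological_mask: np.ndarray
    true_liver_suv: float
    true_marrow_suv: float
    lesion_min_suv: dict[str, float]
    placements: VoiPlacements

    def validate(self) -> None:
        masks = list(self.lesion_masks.values())
        ref = self.liver_mask.astype(bool) | self.physiological_mask.astype(bool)
        for vm in self.vertebra_masks.values():
            ref |= vm.astype(bool)
        seen = np.zeros_like(ref)
        for lid, m in self.lesion_masks.items():
            m = m.astype(bool)
            if not m.any():
                raise ValueError(f"lesion {lid} has no voxels")
            if (m & seen).any():
                raise ValueError(f"lesion {lid} overlaps another lesion")
            if (m & ref).any():
                raise ValueError(f"lesion {lid} overlaps a reference/physiological region")
            seen |= m


# ---------------------------------------------------------------------------
# deterministic parameter draws shared by volume and summary generators

@dataclass(frozen=True)
class _LesionPlan:
    lesion_id: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    min_suv: float
    peak_suv: float


@dataclass(frozen=True)
class _ScanPlan:
    patient_id: str
    stage: str
    liver_suv: float
    marrow_suv: float
    lesions: tuple[_LesionPlan, ...]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    if sd == 0:
        return max(mean, low)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def _cell_bounds(cell: tuple[int, int, int]) -> list[tuple[float, float]]:
    bounds = []
    for ax in range(3):
        lo, hi = _LESION_ZONE[ax]
        w = (hi - lo) / _LESION_CELLS[ax]
        bounds.append((lo + cell[ax] * w, lo + (cell[ax] + 1) * w))
    return bounds


def _plan_cohort(spec: CohortSpec) -> list[_ScanPlan]:
    """Draw all patient-level randomness in a fixed order.

    Both the volumetric and the summary generator consume this single
    stream, so matching specs and seeds yield matching true uptakes and
    lesion minima.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[0])
    plans: list[_ScanPlan] = []
    n_cells = int(np.prod(_LESION_CELLS))
    cells = [
        (i, j, k)
        for i in range(_LESION_CELLS[0])
        for j in range(_LESION_CELLS[1])
        for k in range(_LESION_CELLS[2])
    ]
    for p in range(spec.n_patients):
        pid = f"P{p + 1:02d}"
        liver_base = _truncated_normal(rng, spec.liver_mean, spec.liver_sd, spec.truncate_suv)
        marrow_base = _truncated_normal(rng, spec.marrow_mean, spec.marrow_sd, spec.truncate_suv)
        for stage in spec.stages:
            drift = float(spec.stage_drift.get(stage, 1.0))
            liver = liver_base * drift
            marrow = marrow_base * drift
            ref = liver if spec.lesion_reference == "liver" else marrow
            k = spec.lesion_count(stage)
            chosen = rng.choice(n_cells, size=k, replace=False) if k else []
            lesions = []
            for li, ci in enumerate(chosen):
                bounds = _cell_bounds(cells[int(ci)])
                semi, center = [], []
                for ax in range(3):
                    lo, hi = bounds[ax]
                    max_semi = (hi - lo) / 2.0 - _LESION_MARGIN
                    a = rng.uniform(_MIN_SEMI_AXIS, max(max_semi, _MIN_SEMI_AXIS))
                    a = min(a, max_semi)
                    c = rng.uniform(lo + a + _LESION_MARGIN, hi - a - _LESION_MARGIN)
                    semi.append(float(a))
                    center.append(float(c))
                min_suv = spec.min_fraction(stage) * ref
                lesions.append(
                    _LesionPlan(
                        lesion_id=f"{pid}-{stage}-L{li + 1}",
                        center_mm=tuple(center),
                        semi_axes_mm=tuple(semi),
                        min_suv=min_suv,
                        peak_suv=min_suv * spec.lesion_peak_ratio,
                    )
                )
            plans.append(
                _ScanPlan(
                    patient_id=pid,
                    stage=stage,
                    liver_suv=liver,
                    marrow_suv=marrow,
                    lesions=tuple(lesions),
                )
            )
    return plans


# ---------------------------------------------------------------------------
# rasterization

def _mm_to_index_range(lo: float, hi: float, grid: GridGeometry, ax: int) -> tuple[int, int]:
    centers = grid.voxel_centers(ax)
    idx = np.nonzero((centers >= lo) & (centers < hi))[0]
    if idx.size == 0:
        raise SizingError(f"mm range [{lo}, {hi}] holds no voxel center on axis {ax}")
    return int(idx[0]), int(idx[-1] + 1)


def _box_mask(box_mm, grid: GridGeometry) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    ranges = [_mm_to_index_range(lo, hi, grid, ax) for ax, (lo, hi) in enumerate(box_mm)]
    mask[
        ranges[0][0] : ranges[0][1],
        ranges[1][0] : ranges[1][1],
        ranges[2][0] : ranges[2][1],
    ] = True
    return mask


def _ellipsoid_norm_radius(plan: _LesionPlan, grid: GridGeometry) -> np.ndarray:
    r2 = np.zeros(grid.shape, dtype=np.float64)
    for ax in range(3):
        delta = (grid.voxel_centers(ax) - plan.center_mm[ax]) / plan.semi_axes_mm[ax]
        shape = [1, 1, 1]
        shape[ax] = -1
        r2 = r2 + (delta**2).reshape(shape)
    return np.sqrt(r2)


def _rasterize_scan(
    plan: _ScanPlan, spec: CohortSpec, noise_rng: np.random.Generator
) -> tuple[VolumePair, GroundTruth]:
    grid = spec.grid()
    extent = tuple(n * s for n, s in zip(grid.shape, grid.spacing))

    # CT ---------------------------------------------------------------
    ct = np.full(grid.shape, spec.soft_tissue_hu, dtype=np.float64)
    border = [_mm_to_index_range(_AIR_BORDER_MM, e - _AIR_BORDER_MM, grid, ax) for ax, e in enumerate(extent)]
    body = np.zeros(grid.shape, dtype=bool)
    body[border[0][0] : border[0][1], border[1][0] : border[1][1], border[2][0] : border[2][1]] = True
    ct[~body] = spec.air_hu
    vertebra_masks = {
        name: _box_mask((_VERTEBRA_XY[0], _VERTEBRA_XY[1], zr), grid)
        for name, zr in _VERTEBRA_Z.items()
    }
    for vm in vertebra_masks.values():
        ct[vm] = spec.bone_hu

    # PET --------------------------------------------------------------
    pet = np.full(grid.shape, spec.background_suv, dtype=np.float64)
    liver_mask = _box_mask(_LIVER_BOX, grid)
    pet[liver_mask] = plan.liver_suv
    for vm in vertebra_masks.values():
        pet[vm] = plan.marrow_suv
    physio = np.zeros(grid.shape, dtype=np.float64)
    for ax in range(3):
        delta = grid.voxel_centers(ax) - _PHYSIO_CENTER[ax]
        shape = [1, 1, 1]
        shape[ax] = -1
        physio = physio + (delta**2).reshape(shape)
    physio_mask = physio <= _PHYSIO_RADIUS**2
    pet[physio_mask] = spec.physiological_suv

    lesion_masks: dict[str, np.ndarray] = {}
    lesion_min: dict[str, float] = {}
    for les in plan.lesions:
        r = _ellipsoid_norm_radius(les, grid)
        mask = r <= 1.0
        if not mask.any():
            raise SizingError(f"lesion {les.lesion_id} rasterized to zero voxels")
        # linear fall-off from a central plateau (r <= 0.3) to the rim,
        # then rescale so the realized noiseless minimum is exact
        profile = np.clip((1.0 - r[mask]) / 0.7, 0.0, 1.0)
        lo, hi = profile.min(), profile.max()
        if hi > lo:
            profile = (profile - lo) / (hi - lo)
        else:
            profile = np.ones_like(profile)
        pet[mask] = les.min_suv + profile * (les.peak_suv - les.min_suv)
        lesion_masks[les.lesion_id] = mask
        lesion_min[les.lesion_id] = les.min_suv

    if spec.within_voi_cv > 0:
        pet *= 1.0 + spec.within_voi_cv * noise_rng.standard_normal(grid.shape)
        pet = np.clip(pet, 0.01, None)
        for lid, mask in lesion_masks.items():
            pet[mask] = np.maximum(pet[mask], lesion_min[lid])

    # placements: vertebra search boxes padded by 2 voxels
    boxes = {}
    for name, zr in _VERTEBRA_Z.items():
        ranges = []
        for ax, (lo, hi) in enumerate((_VERTEBRA_XY[0], _VERTEBRA_XY[1], zr)):
            i0, i1 = _mm_to_index_range(lo, hi, grid, ax)
            ranges.append((max(i0 - 2, 0), min(i1 + 2, grid.shape[ax])))
        boxes[name] = tuple(ranges)
    placements = VoiPlacements(liver_center_mm=_LIVER_SPHERE_CENTER, vertebra_boxes=boxes)

    pair = VolumePair(
        ct=ct, pet=pet, grid=grid, patient_id=plan.patient_id, stage=plan.stage
    )
    truth = GroundTruth(
        patient_id=plan.patient_id,
        stage=plan.stage,
        liver_mask=liver_mask,
        vertebra_masks=vertebra_masks,
        lesion_masks=lesion_masks,
        physiological_mask=physio_mask,
        true_liver_suv=plan.liver_suv,
        true_marrow_suv=plan.marrow_suv,
        lesion_min_suv=lesion_min,
        placements=placements,
    )
    truth.validate()
    return pair, truth


def generate_cohort(spec: CohortSpec) -> dict[tuple[str, str], tuple[VolumePair, GroundTruth]]:
    """Generate volumetric phantoms for every patient-stage scan.

    Identical spec and seed yield bit-identical volumes.
    """
    spec.validate()
    noise_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[1])
    out = {}
    for plan in _plan_cohort(spec):
        out[(plan.patient_id, plan.stage)] = _rasterize_scan(plan, spec, noise_rng)
    return out


def generate_summary_cohort(
    spec: CohortSpec,
) -> tuple[list[ReferenceMeasure], list[LesionRecord]]:
    """Volume-free fast path: draw the measures the analysis consumes.

    Per scan, the measured reference mean carries a small sampling jitter
    (cv / sqrt(n_eff) of the true value, n_eff ~ one VOI's voxel count)
    and the within-VOI SD is cv x true mean; lesion minima get
    multiplicative cv noise. Matching spec and seed reproduce the same
    per-patient true means as :func:`generate_cohort`.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    n_eff = 500  # typical voxel count of a 29 mm sphere VOI
    measures: list[ReferenceMeasure] = []
    lesions: list[LesionRecord] = []
    cv = spec.within_voi_cv
    for plan in _plan_cohort(spec):
        for tissue, true in (("liver", plan.liver_suv), ("marrow", plan.marrow_suv)):
            mean = true * (1.0 + cv / np.sqrt(n_eff) * rng.standard_normal()) if cv else true
            measures.append(
                ReferenceMeasure(
                    patient_id=plan.patient_id,
                    stage=plan.stage,
                    tissue=tissue,
                    mean_suv=float(max(mean, 1e-6)),
                    sd_suv=float(cv * true),
                )
            )
        for les in plan.lesions:
            m = les.min_suv * (1.0 + cv * rng.standard_normal()) if cv else les.min_suv
            lesions.append(
                LesionRecord(
                    patient_id=plan.patient_id,
                    stage=plan.stage,
                    lesion_id=les.lesion_id,
                    min_suv=float(max(m, 1e-6)),
                )
            )
    return measures, lesions


def write_cohort(
    cohort: Mapping[tuple[str, str], tuple[VolumePair, GroundTruth]],
    out_dir: str | Path,
) -> Path:
    """Write NIfTI volumes, masks, a manifest CSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_json: dict[str, dict] = {}
    for (pid, stage), (pair, gt) in sorted(cohort.items()):
        stem = f"{pid}_{stage}"
        save_volume(pair.ct, pair.grid, out / f"{stem}_ct.nii.gz")
        save_volume(pair.pet, pair.grid, out / f"{stem}_pet.nii.gz")
        for lid, mask in gt.lesion_masks.items():
            save_volume(mask.astype(np.uint8), pair.grid, out / f"{stem}_lesion_{lid}.nii.gz")
        save_volume(gt.physiological_mask.astype(np.uint8), pair.grid, out / f"{stem}_physio.nii.gz")
        rows.append(
            {
                "patient_id": pid,
                "stage": stage,
                "ct": f"{stem}_ct.nii.gz",
                "pet": f"{stem}_pet.nii.gz",
                "n_lesions": len(gt.lesion_masks),
            }
        )
        truth_json[stem] = {
            "true_liver_suv": gt.true_liver_suv,
            "true_marrow_suv": gt.true_marrow_suv,
            "lesion_min_suv": gt.lesion_min_suv,
            "liver_center_mm": list(gt.placements.liver_center_mm),
            "vertebra_boxes": {k: [list(r) for r in v] for k, v in gt.placements.vertebra_boxes.items()},
        }
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return out
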