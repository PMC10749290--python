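"""Threshold-based lesion segmentation, detection counting and MTV.

A voxel is pathologic when its SUV is *strictly* greater than the
per-patient absolute threshold and it is not covered by the
physiological-uptake exclusion mask (liver, marrow, bladder-like hot
spots — regions a physician would discard by eye). Foreground voxels are
grouped into lesions by 26-connectivity (6-connectivity available), and
labels are assigned deterministically: descending component size, ties
broken by the lexicographically smallest voxel index in the component.

Detection follows the at-least-one-voxel rule: a reported (manually
delineated) lesion counts as detected when any voxel of its mask is
foreground. Metabolic tumour volume (MTV) is the total foreground
volume in ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import GridGeometry
from .thresholds import LesionRecord

__all__ = [
    "SegmentationResult",
    "segment",
    "count_detections",
    "mtv",
    "evaluate_criteria",
]

_STRUCTS = {
    26: np.ones((3, 3, 3), dtype=int),
    6: ndimage.generate_binary_structure(3, 1),
}


@dataclass
class SegmentationResult:
    """Labelled lesion components of one thresholded PET volume."""

    threshold_suv: float
    label_grid: np.ndarray
    grid: GridGeometry
    component_voxels: list[int]
    detected: dict[str, bool] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.component_voxels)

    @property
    def component_volumes_ml(self) -> list[float]:
        v = self.grid.voxel_volume_ml
        return [c * v for c in self.component_voxels]

    @property
    def total_mtv_ml(self) -> float:
        return float(sum(self.component_volumes_ml))

    @property
    def detection_rate(self) -> float | None:
        if not self.detected:
            return None
        return sum(self.detected.values()) / len(self.detected)


def segment(
    pet: np.ndarray,
    threshold_suv: float,
    grid: GridGeometry,
    exclusion_mask: np.ndarray | None = None,
    connectivity: int = 26,
    min_component_voxels: int = 1,
) -> SegmentationResult:
    """Threshold a PET volume and label lesion components.

    ``min_component_voxels`` defaults to 1: single-voxel detections are
    kept, matching the at-least-one-voxel counting rule.
    """
    pet = np.asarray(pet, dtype=np.float64)
    if not np.all(np.isfinite(pet)):
        raise ValueError("non-finite voxels in PET volume")
    if threshold_suv <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold_suv}")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    fg = pet > threshold_suv
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != fg.shape:
            raise ValueError("exclusion mask shape mismatch")
        fg &= ~excl
    raw_labels, n = ndimage.label(fg, structure=_STRUCTS[connectivity])

    # deterministic relabelling: size desc, ties by smallest seed voxel
    order: list[tuple[int, tuple[int, ...], int]] = []
    if n:
        sizes = ndimage.sum_labels(np.ones_like(raw_labels), raw_labels, index=range(1, n + 1))
        seeds = ndimage.find_objects(raw_labels)
        for lab in range(1, n + 1):
            if sizes[lab - 1] < min_component_voxels:
                continue
            sl = seeds[lab - 1]
            idx = np.argwhere(raw_labels[sl] == lab)
            seed = tuple(int(i + s.start) for i, s in zip(idx[0], sl))
            # argwhere scans in C order, so idx[0] is lexicographically least
            order.append((int(sizes[lab - 1]), seed, lab))
        order.sort(key=lambda t: (-t[0], t[1]))
    labels = np.zeros_like(raw_labels)
    component_voxels: list[int] = []
    for new_lab, (size, _seed, old_lab) in enumerate(order, start=1):
        labels[raw_labels == old_lab] = new_lab
        component_voxels.append(size)
    return SegmentationResult(
        threshold_suv=float(threshold_suv),
        label_grid=labels,
        grid=grid,
        component_voxels=component_voxels,
    )


def count_detections(
    result: SegmentationResult, reported: Sequence[LesionRecord]
) -> SegmentationResult:
    """Mark each reported lesion detected iff >= 1 mask voxel is foreground."""
    fg = result.label_grid > 0
    for les in reported:
        if les.mask is None:
            raise ValueError(f"lesion {les.lesion_id} has no mask")
        mask = np.asarray(les.mask, dtype=bool)
        if mask.shape != fg.shape:
            raise ValueError(f"lesion {les.lesion_id} mask is on a different grid")
        result.detected[les.lesion_id] = bool(fg[mask].any())
    return result


def mtv(result: SegmentationResult) -> float:
    """Total metabolic tumour volume in ml (sum of component volumes)."""
    return result.total_mtv_ml


def evaluate_criteria(
    detections: Iterable[tuple[str, str, int, int, int]],
) -> pd.DataFrame:
    """Aggregate per-scan detection counts into a per-criterion table.

    ``detections`` yields (stage, tissue, criterion, n_reported,
    n_detected) tuples, one per scan; the output has one row per
    (stage, tissue, criterion) with summed counts and the detection
    percentage.
    """
    df = pd.DataFrame.from_records(
        list(detections),
        columns=["stage", "tissue", "criterion", "n_reported", "n_detected"],
    )
    if df.empty:
        return df.assign(detected_pct=pd.Series(dtype=float))
    out = (
        df.groupby(["stage", "tissue", "criterion"], as_index=False)[
            ["n_reported", "n_detected"]
        ]
        .sum()
        .sort_values(["stage", "tissue", "criterion"])
        .reset_index(drop=True)
    )
    out["detected_pct"] = np.where(
        out["n_reported"] > 0, 100.0 * out["n_detected"] / out["n_reported"], np.nan
    )
    return out
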