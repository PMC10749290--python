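"""Reference-tissue stability analysis, cohort normal ranges and the
per-scan reference-tissue selection rule.

The segmentation threshold is expressed relative to a reference tissue
(liver or bone marrow), so the whole method rests on that tissue's uptake
being stable across treatment stages and typical for the patient. This
module provides:

* per-patient relative change of uptake vs. baseline (in percent),
* a one-way ANOVA of per-stage mean uptake (stability check),
* the cohort "normal uptake range" = pooled mean +/- 1 SD over every
  patient-stage measurement of a tissue,
* the selection rule: use the liver whenever its uptake lies inside the
  liver normal range; otherwise fall back to bone marrow; if both lie
  outside, the scan is excluded from threshold estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

TISSUES = ("liver", "marrow")

__all__ = [
    "TISSUES",
    "ReferenceMeasure",
    "NormalRange",
    "AnovaResult",
    "ReferenceSelection",
    "relative_change",
    "stage_anova",
    "normal_range",
    "weighted_pooled_mean",
    "select_reference",
]


class MissingBaselineError(ValueError):
    """Relative change requested for a patient without a baseline scan."""


@dataclass(frozen=True)
class ReferenceMeasure:
    """Mean SUV and within-VOI voxel SD of one reference tissue on one scan."""

    patient_id: str
    stage: str
    tissue: str
    mean_suv: float
    sd_suv: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.mean_suv <= 0:
            raise ValueError(f"mean_suv must be > 0, got {self.mean_suv}")
        if self.sd_suv < 0:
            raise ValueError(f"sd_suv must be >= 0, got {self.sd_suv}")


@dataclass(frozen=True)
class NormalRange:
    """Cohort normal uptake range of a tissue: pooled mean +/- 1 SD."""

    tissue: str
    pooled_mean: float
    pooled_sd: float
    n_measurements: int

    @property
    def low(self) -> float:
        return self.pooled_mean - self.pooled_sd

    @property
    def high(self) -> float:
        return self.pooled_mean + self.pooled_sd

    def contains(self, value: float) -> bool:
        """Inclusive bounds: a boundary value counts as within range."""
        return self.low <= value <= self.high


@dataclass(frozen=True)
class AnovaResult:
    tissue: str
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_sizes: dict[str, int]


@dataclass(frozen=True)
class ReferenceSelection:
    """Outcome of the reference-tissue rule for one patient-stage scan."""

    patient_id: str
    stage: str
    selected: Literal["liver", "marrow", "excluded"]
    liver_in_range: bool
    marrow_in_range: bool


def relative_change(suv_stage: float, suv_baseline: float | None) -> float:
    """Percent relative change of uptake with respect to baseline.

    RC = 100 * (SUV_stage - SUV_baseline) / SUV_baseline. Defined only
    for patients with a baseline scan; scale-invariant in the SUVs.
    """
    if suv_baseline is None:
        raise MissingBaselineError("patient has no baseline measurement")
    if suv_baseline <= 0:
        raise ValueError(f"baseline SUV must be > 0, got {suv_baseline}")
    return 100.0 * (suv_stage - suv_baseline) / suv_baseline


def stage_anova(
    measures: Iterable[ReferenceMeasure], tissue: str
) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-patient mean SUV across stages.

    Guarded degenerate case: if every group has zero variance and all
    group means are equal, F is taken as 0 and p as 1 (no evidence of a
    stage effect from constant data).
    """
    groups: dict[str, list[float]] = {}
    for m in measures:
        if m.tissue == tissue:
            groups.setdefault(m.stage, []).append(m.mean_suv)
    if len(groups) < 2:
        raise ValueError(f"need >= 2 stages with data for tissue {tissue!r}")
    for stage, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 measurements")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    all_vals = np.concatenate(arrays)
    if np.ptp(all_vals) == 0.0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
    return AnovaResult(
        tissue=tissue,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        group_means={s: float(np.mean(v)) for s, v in groups.items()},
        group_sds={s: float(np.std(v, ddof=1)) for s, v in groups.items()},
        group_sizes={s: len(v) for s, v in groups.items()},
    )


def normal_range(measures: Iterable[ReferenceMeasure], tissue: str) -> NormalRange:
    """Pooled mean +/- 1 sample SD over all patient-stage measurements.

    The pool runs over every scan of every patient (all stages together);
    the SD uses divisor N-1 because inter-patient spread is a sample
    estimate, in contrast with the within-VOI voxel SD.
    """
    vals = [m.mean_suv for m in measures if m.tissue == tissue]
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 measurements for a normal range, got {len(vals)}"
        )
    arr = np.asarray(vals, dtype=float)
    return NormalRange(
        tissue=tissue,
        pooled_mean=float(arr.mean()),
        pooled_sd=float(arr.std(ddof=1)),
        n_measurements=len(vals),
    )


def weighted_pooled_mean(
    stage_means: Sequence[float], stage_counts: Sequence[int]
) -> float:
    """Scan-count-weighted mean of per-stage means.

    Algebraically identical to pooling every individual measurement and
    taking the flat mean, so the cohort normal-range center can be
    recovered from a per-stage summary table alone.
    """
    means = np.asarray(stage_means, dtype=float)
    counts = np.asarray(stage_counts, dtype=float)
    if means.shape != counts.shape or means.size == 0:
        raise ValueError("stage_means and stage_counts must be equal-length, non-empty")
    if np.any(counts <= 0):
        raise ValueError("stage counts must be positive")
    return float(np.sum(means * counts) / np.sum(counts))


def select_reference(
    liver_measure: ReferenceMeasure,
    marrow_measure: ReferenceMeasure,
    liver_range: NormalRange,
    marrow_range: NormalRange,
) -> ReferenceSelection:
    """Apply the reference-tissue rule to one patient-stage scan.

    Liver has priority whenever its uptake lies within the liver normal
    range (bounds inclusive); otherwise bone marrow is used if within its
    own range; if both lie outside, the scan is excluded from threshold
    estimation. Both in-range flags are returned so that dual-eligible
    scans can be evaluated under either tissue.
    """
    if (liver_measure.patient_id, liver_measure.stage) != (
        marrow_measure.patient_id,
        marrow_measure.stage,
    ):
        raise ValueError("liver and marrow measures must refer to the same scan")
    liver_ok = liver_range.contains(liver_measure.mean_suv)
    marrow_ok = marrow_range.contains(marrow_measure.mean_suv)
    if liver_ok:
        selected = "liver"
    elif marrow_ok:
        selected = "marrow"
    else:
        selected = "excluded"
    return ReferenceSelection(
        patient_id=liver_measure.patient_id,
        stage=liver_measure.stage,
        selected=selected,
        liver_in_range=liver_ok,
        marrow_in_range=marrow_ok,
    )
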