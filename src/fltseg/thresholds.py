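"""Stage-wise relative segmentation thresholds from manually reported lesions.

The central quantities, for each treatment stage and reference tissue:

* **minimum relative threshold** RT — the unweighted mean, over the
  N_stage lesions reported at that stage, of the ratio between each
  lesion's minimum SUV and its patient's reference-tissue uptake:

      RT = (1 / N_stage) * sum_{i,j} SUVmin(j, i) / SUVref(j)

* **absolute per-patient threshold** under criterion n+1 — the relative
  threshold applied to the patient's reference uptake plus n within-VOI
  standard deviations (n = 0, 1, 2):

      T(j) = RT * (SUVref(j) + n * SDref(j))

* **reformulated relative threshold** R~T — the single multiplier that,
  applied to the plain reference uptake, reproduces the criterion-n
  absolute threshold on cohort average:

      R~T = (RT / N_pat) * sum_j (SUVref(j) + n * SDref(j)) / SUVref(j)

  With n = 0 this reduces exactly to RT, and it is nondecreasing in n
  (strictly increasing whenever any within-VOI SD is positive).

Lesions are equally weighted regardless of how many a patient
contributes (the sum runs over lesions); a per-patient-weighted variant
is available for sensitivity analysis. Lesions belonging to patients
whose reference uptake falls outside the cohort normal range are dropped
(and counted) before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceMeasure

logger = logging.getLogger(__name__)

#: criterion number selected per stage (criterion = n + 1 added SDs)
DEFAULT_SELECTED_CRITERION: dict[str, int] = {"baseline": 3, "iPET": 1, "fPET": 2}

__all__ = [
    "DEFAULT_SELECTED_CRITERION",
    "LesionRecord",
    "ThresholdRow",
    "ThresholdTable",
    "minimum_relative_threshold",
    "absolute_threshold",
    "reformulated_threshold",
    "build_threshold_table",
]


class EstimationError(ValueError):
    """No eligible lesions/patients available for a threshold estimate."""


@dataclass(frozen=True)
class LesionRecord:
    """One manually delineated lesion with its minimum SUV.

    ``mask`` (optional) lives on the PET grid; when present, ``min_suv``
    must equal the masked PET minimum (checked where masks are built).
    """

    patient_id: str
    stage: str
    lesion_id: str
    min_suv: float
    mask: object | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.min_suv <= 0:
            raise ValueError(f"min_suv must be > 0, got {self.min_suv}")


def minimum_relative_threshold(
    lesions: Iterable[LesionRecord],
    references: Iterable[ReferenceMeasure],
    tissue: str,
    stage: str,
    eligible_patients: set[str] | None = None,
    per_patient_weighted: bool = False,
) -> tuple[float, int]:
    """Mean lesion-minimum-to-reference ratio over one stage.

    Returns ``(rt, n_lesions_used)``. ``eligible_patients`` restricts the
    average to patients whose reference uptake lies within the normal
    range; lesions of other patients are dropped with a logged count.
    """
    ref_by_patient = {
        m.patient_id: m
        for m in references
        if m.tissue == tissue and m.stage == stage
    }
    ratios_by_patient: dict[str, list[float]] = {}
    dropped = 0
    for les in lesions:
        if les.stage != stage:
            continue
        if eligible_patients is not None and les.patient_id not in eligible_patients:
            dropped += 1
            continue
        ref = ref_by_patient.get(les.patient_id)
        if ref is None:
            raise EstimationError(
                f"no {tissue} reference for patient {les.patient_id} at {stage}"
            )
        ratios_by_patient.setdefault(les.patient_id, []).append(
            les.min_suv / ref.mean_suv
        )
    if dropped:
        logger.info(
            "stage %s / %s: dropped %d lesion(s) of out-of-range patients",
            stage,
            tissue,
            dropped,
        )
    all_ratios = [r for rs in ratios_by_patient.values() for r in rs]
    if not all_ratios:
        raise EstimationError(f"zero eligible lesions at stage {stage} for {tissue}")
    if per_patient_weighted:
        rt = float(np.mean([np.mean(rs) for rs in ratios_by_patient.values()]))
    else:
        rt = float(np.mean(all_ratios))
    return rt, len(all_ratios)


def absolute_threshold(rt: float, measure: ReferenceMeasure, n: int) -> float:
    """Per-patient absolute SUV threshold under criterion n+1.

    T = RT * (mean + n * SD); criterion 1 is n = 0.
    """
    if rt <= 0:
        raise ValueError(f"rt must be > 0, got {rt}")
    if n not in (0, 1, 2):
        raise ValueError(f"n must be 0, 1 or 2, got {n}")
    return rt * (measure.mean_suv + n * measure.sd_suv)


def reformulated_threshold(
    rt: float, measures: Sequence[ReferenceMeasure], n: int
) -> float:
    """Fold criterion-n SD terms back into a single relative multiplier.

    R~T = (RT / N_pat) * sum_j (mean_j + n * sd_j) / mean_j, so that
    R~T * mean_j reproduces the criterion-n absolute threshold on cohort
    average. Identical to RT when n = 0.
    """
    if rt <= 0:
        raise ValueError(f"rt must be > 0, got {rt}")
    if n not in (0, 1, 2):
        raise ValueError(f"n must be 0, 1 or 2, got {n}")
    if len(measures) == 0:
        raise EstimationError("empty patient set for reformulated threshold")
    factors = [(m.mean_suv + n * m.sd_suv) / m.mean_suv for m in measures]
    return rt * float(np.mean(factors))


@dataclass(frozen=True)
class ThresholdRow:
    stage: str
    tissue: str
    rt: float
    rt_tilde: tuple[float, float, float]  # n = 0, 1, 2
    n_lesions: int
    n_patients: int
    selected_criterion: int

    @property
    def final_threshold(self) -> float:
        return self.rt_tilde[self.selected_criterion - 1]


@dataclass
class ThresholdTable:
    rows: list[ThresholdRow]

    def row(self, stage: str, tissue: str) -> ThresholdRow:
        for r in self.rows:
            if r.stage == stage and r.tissue == tissue:
                return r
        raise KeyError((stage, tissue))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; percentages rounded half-up to whole percent for
        display while full precision is kept on the row objects."""

        def pct(x: float) -> int:
            return int(np.floor(100.0 * x + 0.5))

        recs = [
            {
                "stage": r.stage,
                "tissue": r.tissue,
                "rt_pct": pct(r.rt),
                "rt_tilde_n1_pct": pct(r.rt_tilde[1]),
                "rt_tilde_n2_pct": pct(r.rt_tilde[2]),
                "selected_criterion": r.selected_criterion,
                "final_pct": pct(r.final_threshold),
                "n_lesions": r.n_lesions,
                "n_patients": r.n_patients,
            }
            for r in self.rows
        ]
        return pd.DataFrame.from_records(recs)


def build_threshold_table(
    lesions: Iterable[LesionRecord],
    references: Iterable[ReferenceMeasure],
    eligible: Mapping[tuple[str, str], set[str]],
    selected_criterion: Mapping[str, int] | None = None,
    per_patient_weighted: bool = False,
) -> ThresholdTable:
    """Assemble RT and R~T (n = 0, 1, 2) per (stage, tissue).

    ``eligible`` maps (stage, tissue) to the set of patient ids whose
    reference uptake lies within the normal range at that stage; stages
    or tissues with no eligible lesions are skipped (an empty table
    raises). ``selected_criterion`` maps stage to the criterion number
    whose reformulated threshold becomes the final column; the default
    selection is criterion 3 at baseline, 1 at iPET and 2 at fPET.
    """
    lesions = list(lesions)
    references = list(references)
    sel = dict(DEFAULT_SELECTED_CRITERION)
    if selected_criterion:
        for k, v in selected_criterion.items():
            if v not in (1, 2, 3):
                raise ValueError(f"selected criterion must be 1, 2 or 3, got {v}")
            sel[k] = v
    rows: list[ThresholdRow] = []
    stages = sorted({l.stage for l in lesions}, key=lambda s: ("baseline", "iPET", "fPET").index(s))
    for stage in stages:
        for tissue in ("liver", "marrow"):
            patients = eligible.get((stage, tissue), set())
            try:
                rt, n_les = minimum_relative_threshold(
                    lesions,
                    references,
                    tissue,
                    stage,
                    eligible_patients=patients,
                    per_patient_weighted=per_patient_weighted,
                )
            except EstimationError:
                continue
            stage_measures = [
                m
                for m in references
                if m.tissue == tissue and m.stage == stage and m.patient_id in patients
            ]
            rt_tilde = tuple(
                reformulated_threshold(rt, stage_measures, n) for n in (0, 1, 2)
            )
            rows.append(
                ThresholdRow(
                    stage=stage,
                    tissue=tissue,
                    rt=rt,
                    rt_tilde=rt_tilde,
                    n_lesions=n_les,
                    n_patients=len(stage_measures),
                    selected_criterion=sel.get(stage, 1),
                )
            )
    if not rows:
        raise EstimationError("no stage/tissue combination had eligible lesions")
    return ThresholdTable(rows=rows)
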