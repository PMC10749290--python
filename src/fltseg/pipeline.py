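"""End-to-end orchestration: phantoms or a cohort directory in, tables out.

The full analysis chains every stage of the method:

1. obtain scans (generate a synthetic cohort, or load one from disk),
2. measure liver (29 mm sphere) and bone-marrow (T12) reference uptake,
3. check stage stability (per-stage means, one-way ANOVA, relative
   changes vs baseline),
4. compute cohort normal ranges (pooled mean +/- 1 SD) and apply the
   reference-selection rule per scan,
5. estimate minimum and reformulated relative thresholds per stage and
   tissue from the reported lesions of eligible patients,
6. segment every eligible scan under criteria 1-3, count detected
   lesions (at-least-one-voxel rule) and compute MTV under the final
   threshold.

Outputs are plain CSV/JSON written under the configured directory;
rerunning with the same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .imaging import STAGES, GridGeometry, VolumePair, load_volume
from .reference import (
    NormalRange,
    ReferenceMeasure,
    normal_range,
    relative_change,
    select_reference,
    stage_anova,
)
from .segmentation import count_detections, evaluate_criteria, segment
from .synthetic import CohortSpec, GroundTruth, generate_cohort
from .thresholds import (
    DEFAULT_SELECTED_CRITERION,
    EstimationError,
    LesionRecord,
    absolute_threshold,
    build_threshold_table,
)
from .voi import DEFAULT_HU_RANGE, VoiPlacements, reference_measure

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_full_analysis", "load_cohort"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    out_dir: str | Path
    seed: int = 0
    synthetic: Mapping[str, Any] | None = None
    cohort_dir: str | Path | None = None
    liver_voi: str = "sphere29"
    marrow_voi: str = "T12"
    hu_range: tuple[float, float] = DEFAULT_HU_RANGE
    selected_criterion: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SELECTED_CRITERION)
    )
    connectivity: int = 26
    sd_ddof: int = 0
    exclude_patients: tuple[str, ...] = ()
    normal_range_override: Mapping[str, tuple[float, float]] | None = None
    write_labels: bool = False

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "hu_range" in d:
            d["hu_range"] = tuple(d["hu_range"])
        if "exclude_patients" in d:
            d["exclude_patients"] = tuple(d["exclude_patients"])
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """List every violation without running; empty list means valid."""
    problems: list[str] = []
    modes = [config.synthetic is not None, config.cohort_dir is not None]
    if sum(modes) != 1:
        problems.append("exactly one of 'synthetic' or 'cohort_dir' must be set")
    if config.cohort_dir is not None:
        root = Path(config.cohort_dir)
        manifest = root / "manifest.csv"
        if not manifest.exists():
            problems.append(f"manifest not found: {manifest}")
        else:
            df = pd.read_csv(manifest)
            for col in ("patient_id", "stage", "ct", "pet"):
                if col not in df.columns:
                    problems.append(f"manifest missing column '{col}'")
            if "stage" in df.columns:
                bad = sorted(set(df["stage"]) - set(STAGES))
                if bad:
                    problems.append(f"unknown stage names in manifest: {bad}")
            for col in ("ct", "pet"):
                if col in df.columns:
                    for rel in df[col]:
                        if not (root / rel).exists():
                            problems.append(f"missing volume file: {root / rel}")
    if config.synthetic is not None:
        try:
            _spec_from_config(config).validate()
        except Exception as exc:  # surfaced as a violation, not an error
            problems.append(f"synthetic spec invalid: {exc}")
    for stage, crit in config.selected_criterion.items():
        if stage not in STAGES:
            problems.append(f"selected_criterion: unknown stage {stage!r}")
        if crit not in (1, 2, 3):
            problems.append(f"selected_criterion[{stage!r}] must be 1, 2 or 3, got {crit}")
    if config.connectivity not in (6, 26):
        problems.append(f"connectivity must be 6 or 26, got {config.connectivity}")
    if not config.hu_range[0] < config.hu_range[1]:
        problems.append(f"empty HU range {config.hu_range}")
    return problems


def _spec_from_config(config: RunConfig) -> CohortSpec:
    overrides = dict(config.synthetic or {})
    overrides.setdefault("seed", config.seed)
    for key in ("voxel_spacing", "grid_shape", "stages"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return CohortSpec(**overrides)


def load_cohort(
    cohort_dir: str | Path,
) -> dict[tuple[str, str], tuple[VolumePair, GroundTruth]]:
    """Load a cohort written by :func:`fltseg.synthetic.write_cohort`."""
    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    truth = json.loads((root / "ground_truth.json").read_text())
    out: dict[tuple[str, str], tuple[VolumePair, GroundTruth]] = {}
    for rec in manifest.to_dict("records"):
        pid, stage = str(rec["patient_id"]), str(rec["stage"])
        stem = f"{pid}_{stage}"
        ct, geom = load_volume(root / rec["ct"])
        pet, pet_geom = load_volume(root / rec["pet"])
        if not geom.same_grid(pet_geom):
            raise ValueError(f"{stem}: CT and PET grids differ")
        pair = VolumePair(ct=ct, pet=pet, grid=geom, patient_id=pid, stage=stage)
        t = truth[stem]
        lesion_masks = {}
        for lid in t["lesion_min_suv"]:
            m, _ = load_volume(root / f"{stem}_lesion_{lid}.nii.gz")
            lesion_masks[lid] = m > 0.5
        physio, _ = load_volume(root / f"{stem}_physio.nii.gz")
        placements = VoiPlacements(
            liver_center_mm=tuple(t["liver_center_mm"]),
            vertebra_boxes={
                k: tuple(tuple(r) for r in v) for k, v in t["vertebra_boxes"].items()
            },
        )
        gt = GroundTruth(
            patient_id=pid,
            stage=stage,
            liver_mask=np.zeros(geom.shape, dtype=bool),
            vertebra_masks={},
            lesion_masks=lesion_masks,
            physiological_mask=physio > 0.5,
            true_liver_suv=float(t["true_liver_suv"]),
            true_marrow_suv=float(t["true_marrow_suv"]),
            lesion_min_suv={k: float(v) for k, v in t["lesion_min_suv"].items()},
            placements=placements,
        )
        out[(pid, stage)] = (pair, gt)
    return out


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run the whole pipeline; returns the in-memory result bundle.

    Writes the per-scan reference table, stability table, normal ranges,
    threshold table, detection table, MTV table and a machine-readable
    summary under ``config.out_dir``. Any stage failure raises with the
    stage name and the offending scan id.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: input -------------------------------------------------
    if config.synthetic is not None:
        cohort = generate_cohort(_spec_from_config(config))
    else:
        cohort = load_cohort(config.cohort_dir)
    cohort = {
        k: v for k, v in cohort.items() if k[0] not in set(config.exclude_patients)
    }
    if not cohort:
        raise ValueError("input stage: cohort is empty after exclusions")

    # --- stage: VOI statistics ---------------------------------------
    measures: list[ReferenceMeasure] = []
    liver_exclusion_masks: dict[tuple[str, str], np.ndarray] = {}
    for (pid, stage), (pair, gt) in sorted(cohort.items()):
        try:
            liver_m = reference_measure(
                pair, "liver", gt.placements, config.liver_voi, ddof=config.sd_ddof
            )
            marrow_m = reference_measure(
                pair, "marrow", gt.placements, config.marrow_voi, ddof=config.sd_ddof
            )
        except Exception as exc:
            raise RuntimeError(f"VOI stage failed for {pid}/{stage}: {exc}") from exc
        measures.extend([liver_m, marrow_m])
    ref_df = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "stage": m.stage,
                "tissue": m.tissue,
                "mean_suv": round(m.mean_suv, 6),
                "sd_suv": round(m.sd_suv, 6),
            }
            for m in measures
        ]
    )
    ref_df.to_csv(out_dir / "reference_measures.csv", index=False)

    # --- stage: stability --------------------------------------------
    stages_present = sorted(
        {m.stage for m in measures}, key=lambda s: STAGES.index(s)
    )
    stability_rows = []
    anova_results = {}
    for tissue in ("liver", "marrow"):
        if len(stages_present) >= 2:
            try:
                res = stage_anova(measures, tissue)
            except ValueError:
                res = None
        else:
            res = None
        anova_results[tissue] = res
        for stage in stages_present:
            vals = [
                m.mean_suv for m in measures if m.tissue == tissue and m.stage == stage
            ]
            stability_rows.append(
                {
                    "tissue": tissue,
                    "stage": stage,
                    "mean_suv": round(float(np.mean(vals)), 6),
                    "sd_suv": round(float(np.std(vals, ddof=1)), 6) if len(vals) > 1 else 0.0,
                    "n_scans": len(vals),
                    "anova_p": round(res.p_value, 6) if res else np.nan,
                }
            )
    pd.DataFrame(stability_rows).to_csv(out_dir / "stage_stability.csv", index=False)

    rc_rows = []
    by_patient_tissue: dict[tuple[str, str], dict[str, float]] = {}
    for m in measures:
        by_patient_tissue.setdefault((m.patient_id, m.tissue), {})[m.stage] = m.mean_suv
    for (pid, tissue), per_stage in sorted(by_patient_tissue.items()):
        base = per_stage.get("baseline")
        if base is None:
            continue
        for stage in stages_present:
            if stage == "baseline" or stage not in per_stage:
                continue
            rc_rows.append(
                {
                    "patient_id": pid,
                    "tissue": tissue,
                    "stage": stage,
                    "relative_change_pct": round(relative_change(per_stage[stage], base), 6),
                }
            )
    pd.DataFrame(rc_rows).to_csv(out_dir / "relative_changes.csv", index=False)

    # --- stage: normal ranges & reference selection ------------------
    ranges = {t: normal_range(measures, t) for t in ("liver", "marrow")}
    if config.normal_range_override:
        for t, (mean, sd) in config.normal_range_override.items():
            ranges[t] = NormalRange(
                tissue=t, pooled_mean=float(mean), pooled_sd=float(sd), n_measurements=0
            )
    (out_dir / "normal_ranges.json").write_text(
        json.dumps(
            {
                t: {
                    "pooled_mean": r.pooled_mean,
                    "pooled_sd": r.pooled_sd,
                    "low": r.low,
                    "high": r.high,
                    "n_measurements": r.n_measurements,
                }
                for t, r in ranges.items()
            },
            indent=1,
            sort_keys=True,
        )
    )
    by_scan = {
        (m.patient_id, m.stage, m.tissue): m for m in measures
    }
    selections = {}
    sel_rows = []
    for pid, stage in sorted(cohort):
        sel = select_reference(
            by_scan[(pid, stage, "liver")],
            by_scan[(pid, stage, "marrow")],
            ranges["liver"],
            ranges["marrow"],
        )
        selections[(pid, stage)] = sel
        sel_rows.append(
            {
                "patient_id": pid,
                "stage": stage,
                "selected": sel.selected,
                "liver_in_range": sel.liver_in_range,
                "marrow_in_range": sel.marrow_in_range,
            }
        )
        if sel.selected == "excluded":
            logger.info("scan %s/%s excluded: both tissues out of range", pid, stage)
    pd.DataFrame(sel_rows).to_csv(out_dir / "reference_selection.csv", index=False)

    eligible: dict[tuple[str, str], set[str]] = {}
    for (pid, stage), sel in selections.items():
        if sel.liver_in_range:
            eligible.setdefault((stage, "liver"), set()).add(pid)
        if sel.marrow_in_range:
            eligible.setdefault((stage, "marrow"), set()).add(pid)

    # --- stage: lesion records ---------------------------------------
    lesions: list[LesionRecord] = []
    for (pid, stage), (pair, gt) in sorted(cohort.items()):
        for lid, mask in sorted(gt.lesion_masks.items()):
            min_suv = float(pair.pet[mask].min())
            lesions.append(
                LesionRecord(
                    patient_id=pid, stage=stage, lesion_id=lid, min_suv=min_suv, mask=mask
                )
            )

    # --- stage: thresholds -------------------------------------------
    try:
        table = build_threshold_table(
            lesions, measures, eligible, selected_criterion=config.selected_criterion
        )
    except EstimationError as exc:
        raise EstimationError(f"threshold stage failed: {exc}") from exc
    table.to_frame().to_csv(out_dir / "threshold_table.csv", index=False)
    (out_dir / "threshold_table.json").write_text(
        json.dumps(
            [
                {
                    "stage": r.stage,
                    "tissue": r.tissue,
                    "rt": r.rt,
                    "rt_tilde": list(r.rt_tilde),
                    "n_lesions": r.n_lesions,
                    "n_patients": r.n_patients,
                    "selected_criterion": r.selected_criterion,
                    "final_threshold": r.final_threshold,
                }
                for r in table.rows
            ],
            indent=1,
            sort_keys=True,
        )
    )

    # --- stage: segmentation & detection -----------------------------
    det_records = []
    mtv_rows = []
    for (pid, stage), (pair, gt) in sorted(cohort.items()):
        scan_lesions = [l for l in lesions if l.patient_id == pid and l.stage == stage]
        exclusion = gt.physiological_mask.astype(bool) | gt.liver_mask.astype(bool)
        for vm in gt.vertebra_masks.values():
            exclusion |= vm.astype(bool)
        for tissue in ("liver", "marrow"):
            if pid not in eligible.get((stage, tissue), set()):
                continue
            try:
                row = table.row(stage, tissue)
            except KeyError:
                continue
            measure = by_scan[(pid, stage, tissue)]
            for n in (0, 1, 2):
                thr = absolute_threshold(row.rt, measure, n)
                result = segment(
                    pair.pet, thr, pair.grid, exclusion, connectivity=config.connectivity
                )
                if scan_lesions:
                    count_detections(result, scan_lesions)
                    det_records.append(
                        (
                            stage,
                            tissue,
                            n + 1,
                            len(scan_lesions),
                            sum(result.detected.values()),
                        )
                    )
                if n + 1 == row.selected_criterion:
                    final_thr = row.final_threshold * measure.mean_suv
                    final = segment(
                        pair.pet,
                        final_thr,
                        pair.grid,
                        exclusion,
                        connectivity=config.connectivity,
                    )
                    mtv_rows.append(
                        {
                            "patient_id": pid,
                            "stage": stage,
                            "tissue": tissue,
                            "threshold_suv": round(final_thr, 6),
                            "n_components": final.n_components,
                            "total_mtv_ml": round(final.total_mtv_ml, 6),
                        }
                    )
                    if config.write_labels:
                        from .imaging import save_volume

                        save_volume(
                            final.label_grid.astype(np.int16),
                            pair.grid,
                            out_dir / f"{pid}_{stage}_{tissue}_labels.nii.gz",
                        )
    detection_df = evaluate_criteria(det_records)
    detection_df.to_csv(out_dir / "detection_table.csv", index=False)
    mtv_df = pd.DataFrame(mtv_rows)
    mtv_df.to_csv(out_dir / "mtv_table.csv", index=False)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_scans": len(cohort),
        "n_lesions": len(lesions),
        "normal_ranges": {
            t: [ranges[t].pooled_mean, ranges[t].pooled_sd] for t in ranges
        },
        "anova_p": {
            t: (anova_results[t].p_value if anova_results[t] else None)
            for t in anova_results
        },
        "excluded_scans": [
            f"{pid}/{stage}"
            for (pid, stage), sel in sorted(selections.items())
            if sel.selected == "excluded"
        ],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    return {
        "measures": measures,
        "ranges": ranges,
        "anova": anova_results,
        "selections": selections,
        "eligible": eligible,
        "lesions": lesions,
        "threshold_table": table,
        "detection_table": detection_df,
        "mtv_table": mtv_df,
        "summary": summary,
    }
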