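"""Minimum relative thresholds, criteria and reformulated thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fltseg import (
    CohortSpec,
    LesionRecord,
    ReferenceMeasure,
    absolute_threshold,
    build_threshold_table,
    generate_summary_cohort,
    minimum_relative_threshold,
    reformulated_threshold,
)
from fltseg.thresholds import EstimationError
from conftest import oracle_mean_of_ratios


def _ref(pid, stage, tissue, mean, sd=0.0):
    return ReferenceMeasure(pid, stage, tissue, mean, sd)


def _les(pid, stage, lid, min_suv):
    return LesionRecord(pid, stage, lid, min_suv)


class TestMinimumRelativeThreshold:
    def test_ratio_identity(self):
        refs = [_ref("P1", "baseline", "liver", 5.0), _ref("P2", "baseline", "liver", 4.0)]
        lesions = [_les("P1", "baseline", "a", 5.0), _les("P2", "baseline", "b", 4.0)]
        rt, n = minimum_relative_threshold(lesions, refs, "liver", "baseline")
        assert rt == pytest.approx(1.0)
        assert n == 2

    def test_single_lesion(self):
        rt, _ = minimum_relative_threshold(
            [_les("P1", "baseline", "a", 2.5)],
            [_ref("P1", "baseline", "liver", 5.0)],
            "liver",
            "baseline",
        )
        assert rt == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(31)
        refs, lesions, mins_by_patient, ref_by_patient = [], [], {}, {}
        for p in range(10):
            pid = f"P{p}"
            ref = rng.uniform(3, 8)
            refs.append(_ref(pid, "iPET", "marrow", ref))
            ref_by_patient[pid] = ref
            mins = rng.uniform(1, 4, size=5)
            mins_by_patient[pid] = list(mins)
            for i, m in enumerate(mins):
                lesions.append(_les(pid, "iPET", f"{pid}-{i}", float(m)))
        rt, n = minimum_relative_threshold(lesions, refs, "marrow", "iPET")
        assert n == 50
        assert rt == pytest.approx(oracle_mean_of_ratios(mins_by_patient, ref_by_patient), rel=1e-12)

    def test_ineligible_patients_dropped(self):
        refs = [_ref("P1", "baseline", "liver", 5.0), _ref("P2", "baseline", "liver", 5.0)]
        lesions = [_les("P1", "baseline", "a", 2.5), _les("P2", "baseline", "b", 5.0)]
        rt, n = minimum_relative_threshold(
            lesions, refs, "liver", "baseline", eligible_patients={"P1"}
        )
        assert (rt, n) == (pytest.approx(0.5), 1)

    def test_zero_eligible_lesions_raises(self):
        with pytest.raises(EstimationError, match="baseline"):
            minimum_relative_threshold(
                [_les("P1", "baseline", "a", 2.0)],
                [_ref("P1", "baseline", "liver", 5.0)],
                "liver",
                "baseline",
                eligible_patients=set(),
            )

    @settings(max_examples=40, derandomize=True)
    @given(a=st.floats(0.1, 10.0))
    def test_scale_invariance(self, a):
        refs = [_ref("P1", "fPET", "liver", 5.0)]
        lesions = [_les("P1", "fPET", "x", 2.0)]
        rt0, _ = minimum_relative_threshold(lesions, refs, "liver", "fPET")
        refs_s = [_ref("P1", "fPET", "liver", 5.0 * a)]
        lesions_s = [_les("P1", "fPET", "x", 2.0 * a)]
        rt1, _ = minimum_relative_threshold(lesions_s, refs_s, "liver", "fPET")
        assert rt1 == pytest.approx(rt0, rel=1e-9)


class TestAbsoluteThreshold:
    def test_criterion_one(self):
        m = _ref("P1", "baseline", "liver", 5.0, 0.5)
        assert absolute_threshold(0.33, m, 0) == pytest.approx(1.65)

    def test_criterion_three(self):
        m = _ref("P1", "baseline", "liver", 5.0, 0.5)
        assert absolute_threshold(0.49, m, 2) == pytest.approx(2.94)

    def test_zero_sd_collapses_criteria(self):
        m = _ref("P1", "iPET", "marrow", 6.0, 0.0)
        vals = [absolute_threshold(0.4, m, n) for n in (0, 1, 2)]
        assert vals[0] == vals[1] == vals[2]

    def test_nondecreasing_in_n(self):
        m = _ref("P1", "fPET", "liver", 5.0, 0.7)
        vals = [absolute_threshold(0.3, m, n) for n in (0, 1, 2)]
        assert vals[0] < vals[1] < vals[2]


class TestReformulatedThreshold:
    def test_n_zero_identity_exact(self):
        rng = np.random.default_rng(3)
        ms = [
            _ref(f"P{i}", "baseline", "liver", rng.uniform(3, 8), rng.uniform(0, 1))
            for i in range(20)
        ]
        rt = 0.42
        assert reformulated_threshold(rt, ms, 0) == rt

    def test_single_patient(self):
        m = _ref("P1", "baseline", "liver", 5.0, 0.5)
        assert reformulated_threshold(0.49, [m], 2) == pytest.approx(0.588)

    def test_matches_per_patient_algebraic_solve(self):
        # solve RT*(SUV + SD) = x*SUV per patient, then average x
        rng = np.random.default_rng(8)
        ms = [
            _ref(f"P{i}", "iPET", "marrow", rng.uniform(4, 10), rng.uniform(0, 2))
            for i in range(20)
        ]
        rt = 0.33
        per_patient = [rt * (m.mean_suv + m.sd_suv) / m.mean_suv for m in ms]
        assert reformulated_threshold(rt, ms, 1) == pytest.approx(
            float(np.mean(per_patient)), rel=1e-12
        )

    def test_monotone_in_n_strict_with_positive_sd(self):
        ms = [_ref("P1", "fPET", "liver", 5.0, 0.3), _ref("P2", "fPET", "liver", 6.0, 0.0)]
        vals = [reformulated_threshold(0.3, ms, n) for n in (0, 1, 2)]
        assert vals[0] < vals[1] < vals[2]

    def test_cohort_mean_consistency(self):
        # defining property: mean_j [RT*(mean+n*sd) - RT~*mean] = 0
        rng = np.random.default_rng(12)
        ms = [
            _ref(f"P{i}", "baseline", "liver", rng.uniform(3, 8), rng.uniform(0, 1.5))
            for i in range(30)
        ]
        rt = 0.5
        for n in (0, 1, 2):
            rt_t = reformulated_threshold(rt, ms, n)
            # the criterion-n absolute threshold, expressed relative to each
            # patient's reference uptake, averages exactly to rt_tilde
            assert np.mean(
                [absolute_threshold(rt, m, n) / m.mean_suv for m in ms]
            ) == pytest.approx(rt_t, rel=1e-12)

    def test_empty_patient_set_raises(self):
        with pytest.raises(EstimationError):
            reformulated_threshold(0.4, [], 1)


class TestBuildThresholdTable:
    def _summary(self, **kw):
        spec = CohortSpec(n_patients=8, seed=2, **kw)
        measures, lesions = generate_summary_cohort(spec)
        eligible = {
            (stage, tissue): {m.patient_id for m in measures if m.tissue == tissue}
            for stage in spec.stages
            for tissue in ("liver", "marrow")
        }
        return measures, lesions, eligible

    def test_selected_n0_final_equals_rt(self):
        measures, lesions, eligible = self._summary()
        table = build_threshold_table(
            lesions, measures, eligible, selected_criterion={s: 1 for s in ("baseline", "iPET", "fPET")}
        )
        for row in table.rows:
            assert row.final_threshold == row.rt

    def test_noiseless_planted_fraction_recovered(self):
        measures, lesions, eligible = self._summary(
            within_voi_cv=0.0, lesion_min_fraction=0.5
        )
        table = build_threshold_table(lesions, measures, eligible)
        for stage in ("baseline", "iPET", "fPET"):
            assert table.row(stage, "liver").rt == pytest.approx(0.5, abs=1e-9)

    def test_display_rounds_to_whole_percent(self):
        measures, lesions, eligible = self._summary(within_voi_cv=0.0, lesion_min_fraction=0.375)
        table = build_threshold_table(lesions, measures, eligible)
        df = table.to_frame()
        assert df["rt_pct"].dtype.kind == "i"
        row = df[(df.stage == "baseline") & (df.tissue == "liver")].iloc[0]
        assert row.rt_pct == 38  # 37.5 rounds half-up
        # full precision preserved on the row objects
        assert table.row("baseline", "liver").rt == pytest.approx(0.375)

    def test_rt_tilde_monotone_rows(self):
        measures, lesions, eligible = self._summary()
        table = build_threshold_table(lesions, measures, eligible)
        for row in table.rows:
            assert row.rt_tilde[0] <= row.rt_tilde[1] <= row.rt_tilde[2]
            assert row.rt_tilde[0] == row.rt
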