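"""Threshold segmentation, detection counting and tumour volume."""

import numpy as np
import pytest

from fltseg import GridGeometry, LesionRecord, count_detections, mtv, segment
from fltseg.segmentation import evaluate_criteria
from conftest import oracle_component_count


GRID = GridGeometry((20, 20, 20), (2.0, 2.0, 2.0))


class TestSegment:
    def test_threshold_above_max_zero_components(self):
        pet = np.random.default_rng(0).uniform(0, 5, size=GRID.shape)
        res = segment(pet, 10.0, GRID)
        assert res.n_components == 0
        assert res.total_mtv_ml == 0.0

    def test_single_blob_exact_voxels(self):
        pet = np.full(GRID.shape, 1.0)
        pet[5:8, 5:8, 5:8] = 4.0
        res = segment(pet, 2.0, GRID)
        assert res.n_components == 1
        assert res.component_voxels == [27]
        assert (res.label_grid[5:8, 5:8, 5:8] == 1).all()

    def test_strict_inequality_boundary_is_background(self):
        pet = np.full(GRID.shape, 1.0)
        pet[3, 3, 3] = 2.0
        res = segment(pet, 2.0, GRID)
        assert res.n_components == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_component_count_matches_flood_fill(self, connectivity):
        rng = np.random.default_rng(23)
        for _ in range(10):
            field = rng.random((12, 12, 12)) > 0.72
            pet = np.where(field, 5.0, 1.0)
            res = segment(pet, 2.0, GridGeometry((12, 12, 12), (1.0, 1.0, 1.0)),
                          connectivity=connectivity)
            assert res.n_components == oracle_component_count(field, connectivity)

    def test_exclusion_mask_removes_voxels(self):
        pet = np.full(GRID.shape, 1.0)
        pet[5:8, 5:8, 5:8] = 4.0
        excl = np.zeros(GRID.shape, dtype=bool)
        excl[5:8, 5:8, 5:8] = True
        res = segment(pet, 2.0, GRID, exclusion_mask=excl)
        assert res.n_components == 0

    def test_foreground_nonincreasing_in_threshold(self):
        pet = np.random.default_rng(5).uniform(0, 10, size=GRID.shape)
        counts = [
            int((segment(pet, t, GRID).label_grid > 0).sum())
            for t in np.linspace(0.5, 9.5, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_labels_partition_foreground(self):
        rng = np.random.default_rng(7)
        pet = np.where(rng.random(GRID.shape) > 0.7, 5.0, 1.0)
        res = segment(pet, 2.0, GRID)
        fg = pet > 2.0
        assert ((res.label_grid > 0) == fg).all()
        assert sum(res.component_voxels) == int(fg.sum())

    def test_deterministic_label_order_by_size(self):
        pet = np.full(GRID.shape, 1.0)
        pet[1:3, 1:3, 1:3] = 5.0  # 8 voxels
        pet[10:14, 10:14, 10:14] = 5.0  # 64 voxels
        res = segment(pet, 2.0, GRID)
        assert res.component_voxels == [64, 8]
        assert res.label_grid[10, 10, 10] == 1
        assert res.label_grid[1, 1, 1] == 2

    def test_non_finite_rejected(self):
        pet = np.full(GRID.shape, 1.0)
        pet[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            segment(pet, 1.0, GRID)


class TestDetections:
    def _blob_pet(self):
        pet = np.full(GRID.shape, 1.0)
        pet[5:8, 5:8, 5:8] = 4.0
        return pet

    def _lesion(self, lid, slc):
        mask = np.zeros(GRID.shape, dtype=bool)
        mask[slc] = True
        return LesionRecord("P1", "baseline", lid, 1.0, mask=mask)

    def test_fully_superthreshold_lesions_all_detected(self):
        res = segment(self._blob_pet(), 2.0, GRID)
        les = self._lesion("a", np.s_[5:8, 5:8, 5:8])
        res = count_detections(res, [les])
        assert res.detected == {"a": True}
        assert res.detection_rate == 1.0

    def test_subthreshold_lesion_not_detected(self):
        res = segment(self._blob_pet(), 2.0, GRID)
        les = self._lesion("cold", np.s_[15:18, 15:18, 15:18])
        res = count_detections(res, [les])
        assert res.detected == {"cold": False}

    def test_single_overlapping_voxel_counts(self):
        res = segment(self._blob_pet(), 2.0, GRID)
        les = self._lesion("edge", np.s_[7:10, 7:10, 7:10])  # overlaps one corner
        res = count_detections(res, [les])
        assert res.detected["edge"]


class TestMtv:
    def test_zero_components_zero_ml(self):
        res = segment(np.full(GRID.shape, 1.0), 2.0, GRID)
        assert mtv(res) == 0.0

    def test_thousand_voxels_at_2mm(self):
        pet = np.full(GRID.shape, 1.0)
        pet.ravel()[:1000] = 5.0
        res = segment(pet, 2.0, GRID)
        assert mtv(res) == pytest.approx(8.0)  # 1000 * 8 mm^3

    def test_planted_ellipsoid_volume_within_5pct(self):
        # 1 mm grid, ellipsoid semi-axes (10, 8, 6) mm
        grid = GridGeometry((30, 26, 22), (1.0, 1.0, 1.0))
        a, b, c = 10.0, 8.0, 6.0
        center = (14.5, 12.5, 10.5)
        r2 = np.zeros(grid.shape)
        for ax, (cc, s) in enumerate(zip(center, (a, b, c))):
            delta = (grid.voxel_centers(ax) - cc) / s
            shape = [1, 1, 1]
            shape[ax] = -1
            r2 = r2 + (delta**2).reshape(shape)
        pet = np.where(r2 <= 1.0, 5.0, 0.5)
        res = segment(pet, 1.0, grid)
        analytic = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        assert abs(mtv(res) - analytic) / analytic < 0.05


class TestEvaluateCriteria:
    def test_detection_counts_aggregated(self):
        recs = [
            ("baseline", "liver", 1, 3, 3),
            ("baseline", "liver", 1, 2, 1),
            ("baseline", "liver", 2, 5, 3),
        ]
        df = evaluate_criteria(recs)
        row1 = df[(df.criterion == 1)].iloc[0]
        assert (row1.n_reported, row1.n_detected) == (5, 4)
        assert row1.detected_pct == pytest.approx(80.0)

    def test_detections_nonincreasing_across_criteria(self, small_cohort):
        # higher criteria mean higher thresholds, hence fewer detections
        _, cohort = small_cohort
        for (pid, stage), (pair, gt) in cohort.items():
            if not gt.lesion_masks:
                continue
            lesions = [
                LesionRecord(pid, stage, lid, float(pair.pet[m].min()), mask=m)
                for lid, m in gt.lesion_masks.items()
            ]
            excl = gt.physiological_mask | gt.liver_mask
            for vm in gt.vertebra_masks.values():
                excl |= vm
            ref, sd = gt.true_liver_suv, 0.05 * gt.true_liver_suv
            detected = []
            for n in (0, 1, 2):
                thr = 0.5 * (ref + n * sd)
                res = count_detections(segment(pair.pet, thr, pair.grid, excl), lesions)
                detected.append(sum(res.detected.values()))
            assert detected[0] >= detected[1] >= detected[2]

    def test_margin_engineered_counts_strictly_decrease(self):
        # three lesions whose minima interleave the criterion thresholds
        grid = GridGeometry((24, 8, 8), (2.0, 2.0, 2.0))
        pet = np.full(grid.shape, 0.5)
        ref_mean, ref_sd, rt = 5.0, 1.0, 0.5
        thr = [rt * (ref_mean + n * ref_sd) for n in (0, 1, 2)]  # 2.5, 3.0, 3.5
        minima = [2.75, 3.25, 3.75]  # detected by criteria <=1, <=2, <=3
        lesions = []
        for i, m in enumerate(minima):
            slc = np.s_[2 + 8 * i : 6 + 8 * i, 2:6, 2:6]
            pet[slc] = m
            mask = np.zeros(grid.shape, dtype=bool)
            mask[slc] = True
            lesions.append(LesionRecord("P1", "baseline", f"L{i}", m, mask=mask))
        counts = []
        for t in thr:
            res = count_detections(segment(pet, t, grid), lesions)
            counts.append(sum(res.detected.values()))
        assert counts == [3, 2, 1]
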