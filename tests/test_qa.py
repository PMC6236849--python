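"""TRE, contour QA and DVH metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbctdose.dose import DoseGrid
from cbctdose.grids import Geometry, ScalarGrid, mask_from_bool
from cbctdose.landmarks import LandmarkSet
from cbctdose.qa import (
    compute_tre,
    contour_metrics,
    course_report,
    dvh_metrics,
    report_summary,
)


def make_dose(geom, values):
    return DoseGrid(ScalarGrid(geom, values, "Gy"))


class TestComputeTRE:
    def test_coincident_pairs_give_zero(self):
        pts = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        rep = compute_tre(LandmarkSet(pts, pts))
        assert rep.mean_mm == 0.0
        assert rep.n == 2

    def test_raw_distance_without_field(self):
        fixed = np.zeros((3, 3))
        moving = fixed + np.array([3.0, 0.0, 4.0])  # distance 5 each
        rep = compute_tre(LandmarkSet(fixed, moving))
        np.testing.assert_allclose(rep.errors_mm, 5.0)

    def test_exact_field_recovers_below_half_voxel(self, phantom32, spec32):
        lm = phantom32.landmarks[5]
        rep = compute_tre(lm, phantom32.gt_fields[5])
        assert rep.mean_mm < 0.5 * min(spec32.spacing_mm)

    def test_pooling_across_cases(self):
        a = LandmarkSet(np.zeros((2, 3)), np.zeros((2, 3)) + [1.0, 0, 0])
        b = LandmarkSet(np.zeros((3, 3)), np.zeros((3, 3)) + [3.0, 0, 0])
        rep = compute_tre([a, b])
        assert rep.n == 5
        assert rep.mean_mm == pytest.approx((2 * 1 + 3 * 3) / 5)
        assert len(rep.per_case) == 2


class TestContourMetrics:
    def geom(self):
        return Geometry((0, 0, 0), (1, 1, 1), (20, 20, 20))

    def cube(self, lo, hi):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return mask_from_bool(self.geom(), m, "cube")

    def test_identical_masks(self):
        a = self.cube((5, 5, 5), (15, 15, 15))
        rep = contour_metrics(a, a)
        assert rep.dice == 1.0
        assert rep.msd_mm == 0.0
        assert not rep.volume_flag and not rep.com_flag

    def test_half_overlapping_cubes_dice(self):
        # 10x10x10 cubes overlapping in half their volume -> DICE 0.5 exactly
        a = self.cube((0, 5, 5), (10, 15, 15))
        b = self.cube((5, 5, 5), (15, 15, 15))
        rep = contour_metrics(a, b)
        assert rep.dice == pytest.approx(2 * 500 / (1000 + 1000))

    def test_dice_symmetry(self):
        a = self.cube((0, 5, 5), (10, 15, 15))
        b = self.cube((3, 5, 5), (15, 15, 15))
        assert contour_metrics(a, b).dice == contour_metrics(b, a).dice
        assert contour_metrics(a, b).msd_mm == pytest.approx(
            contour_metrics(b, a).msd_mm)

    @pytest.mark.parametrize("scale,expected_flag", [
        (1.09, False),   # +9 % volume: below threshold
        (1.12, True),    # +12 %: above
        (0.88, True),    # -12 %: magnitude above
    ])
    def test_volume_flag_boundary(self, scale, expected_flag):
        a = self.cube((2, 2, 2), (12, 12, 12))  # 1000 voxels
        n_target = int(round(1000 * scale))
        m = np.zeros((20, 20, 20), dtype=bool)
        m.ravel()[np.arange(20 ** 3)[a.mask.ravel().argsort()[::-1][:n_target]]] = True
        # build B as A plus/minus voxels adjacent in the flat order
        b_mask = np.zeros((20, 20, 20), dtype=bool)
        flat_a = np.flatnonzero(a.mask.ravel())
        if n_target >= 1000:
            extra = np.flatnonzero(~a.mask.ravel())[: n_target - 1000]
            keep = np.concatenate([flat_a, extra])
        else:
            keep = flat_a[:n_target]
        b_mask.ravel()[keep] = True
        b = mask_from_bool(self.geom(), b_mask, "B")
        rep = contour_metrics(a, b)
        assert rep.volume_flag is expected_flag

    @pytest.mark.parametrize("shift,expected_flag", [(2, False), (4, True)])
    def test_com_flag_boundary_voxelized(self, shift, expected_flag):
        a = self.cube((2, 5, 5), (12, 15, 15))
        b = self.cube((2 + shift, 5, 5), (12 + shift, 15, 15))
        rep = contour_metrics(a, b)
        assert rep.com_shift_mm == pytest.approx(float(shift))
        assert rep.com_flag is expected_flag

    def test_com_flag_strictly_above_3mm(self):
        # sub-voxel COM shifts via anisotropic spacing: 2.9 no flag, 3.1 flag
        geom = Geometry((0, 0, 0), (0.1, 1, 1), (100, 10, 10))
        m = np.zeros((100, 10, 10), dtype=bool)
        m[10:40, 2:8, 2:8] = True
        a = mask_from_bool(geom, m, "A")
        for shift_vox, expected in [(29, False), (31, True)]:
            m2 = np.zeros((100, 10, 10), dtype=bool)
            m2[10 + shift_vox:40 + shift_vox, 2:8, 2:8] = True
            rep = contour_metrics(a, mask_from_bool(geom, m2, "B"))
            assert rep.com_shift_mm == pytest.approx(shift_vox * 0.1)
            assert rep.com_flag is expected

    def test_both_empty_rejected(self):
        empty = mask_from_bool(self.geom(), np.zeros((20, 20, 20), bool), "E")
        with pytest.raises(ValueError, match="empty"):
            contour_metrics(empty, empty)

    def test_msd_known_value(self):
        # two parallel 1-voxel slabs 4 mm apart: every surface voxel of one
        # is exactly 4 mm from the other's surface
        a = self.cube((5, 0, 0), (6, 20, 20))
        b = self.cube((9, 0, 0), (10, 20, 20))
        rep = contour_metrics(a, b)
        assert rep.msd_mm == pytest.approx(4.0)


class TestDVHMetrics:
    def geom(self, n=16):
        return Geometry((0, 0, 0), (1, 1, 1), (n, n, n))

    def full_roi(self, n=16):
        return mask_from_bool(self.geom(n), np.ones((n, n, n), bool), "R")

    def test_uniform_dose(self):
        d = make_dose(self.geom(), np.full((16, 16, 16), 50.0))
        m = dvh_metrics(d, self.full_roi())
        assert m.d_gy[99] == m.d_gy[95] == m.d_gy[90] == 50.0
        assert m.max_gy == m.mean_gy == 50.0
        assert m.v_pct[20.0] == 100.0

    def test_linear_ramp_d90_and_v20(self):
        # SI ramp 0 -> 100 Gy: D90 = 10 Gy, V20 = 80 % (one-voxel tolerance)
        n = 50
        geom = Geometry((0, 0, 0), (1, 1, 1), (4, 4, n))
        vals = np.broadcast_to(np.linspace(0.0, 100.0, n), (4, 4, n)).copy()
        d = make_dose(geom, vals)
        roi = mask_from_bool(geom, np.ones((4, 4, n), bool), "R")
        m = dvh_metrics(d, roi)
        assert m.d_gy[90] == pytest.approx(10.0, abs=100.0 / (n - 1))
        assert m.v_pct[20.0] == pytest.approx(80.0, abs=100.0 / n)

    def test_matches_brute_force_sort_oracle(self, rng):
        vals = rng.uniform(0, 70, size=(16, 16, 16))
        sel = rng.random((16, 16, 16)) > 0.4
        d = make_dose(self.geom(), vals)
        roi = mask_from_bool(self.geom(), sel, "R")
        m = dvh_metrics(d, roi)
        doses = vals[sel]
        for q in (99, 95, 90):
            assert m.d_gy[q] == np.quantile(doses, 1 - q / 100.0, method="linear")
        assert m.v_pct[20.0] == 100.0 * np.mean(doses >= 20.0)
        assert m.max_gy == doses.max()

    def test_percent_delta_formula(self):
        d = make_dose(self.geom(), np.full((16, 16, 16), 96.5))
        plan = make_dose(self.geom(), np.full((16, 16, 16), 100.0))
        m = dvh_metrics(d, self.full_roi(), plan_dose=plan)
        assert m.percent_of_plan["D99"] == pytest.approx(96.5)
        assert m.percent_delta["D99"] == pytest.approx(-3.5)

    def test_empty_roi_rejected(self):
        d = make_dose(self.geom(), np.zeros((16, 16, 16)))
        roi = mask_from_bool(self.geom(), np.zeros((16, 16, 16), bool), "E")
        with pytest.raises(ValueError, match="empty"):
            dvh_metrics(d, roi)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_dq_ordering_property(self, seed):
        r = np.random.default_rng(seed)
        vals = r.gamma(2.0, 5.0, size=(8, 8, 8))
        sel = r.random((8, 8, 8)) > 0.5
        if not sel.any():
            sel[0, 0, 0] = True
        geom = Geometry((0, 0, 0), (1, 1, 1), (8, 8, 8))
        m = dvh_metrics(make_dose(geom, vals), mask_from_bool(geom, sel, "R"))
        assert m.d_gy[99] <= m.d_gy[95] <= m.d_gy[90] <= m.max_gy


class TestCourseReport:
    def geom(self):
        return Geometry((0, 0, 0), (2, 2, 2), (10, 10, 10))

    def test_identical_fraction_has_zero_deltas(self, rng):
        geom = self.geom()
        plan = make_dose(geom, rng.uniform(1, 10, size=(10, 10, 10)))
        daily = DoseGrid(plan.grid.with_values(plan.values / 3.0))
        rois = {"GTV": mask_from_bool(geom, np.ones((10, 10, 10), bool), "GTV")}
        df = course_report(plan, {1: daily}, None, rois, n_fractions_plan=3)
        deltas = df["percent_delta"].to_numpy(dtype=float)
        deltas = deltas[~np.isnan(deltas)]  # V20 undefined when plan V20 is 0
        assert np.allclose(deltas, 0.0, atol=1e-9)

    def test_empty_roi_list_gives_header_only(self, rng):
        geom = self.geom()
        plan = make_dose(geom, rng.uniform(1, 10, size=(10, 10, 10)))
        df = course_report(plan, {}, None, {})
        assert df.empty
        assert list(df.columns) == ["fraction", "roi", "metric", "plan", "tx",
                                    "percent_delta"]
        assert "no ROIs" in report_summary(df)

    def test_systematic_underdose_is_directional(self, rng):
        # cold daily dose: every percent delta negative
        geom = self.geom()
        plan = make_dose(geom, rng.uniform(5, 10, size=(10, 10, 10)))
        daily = DoseGrid(plan.grid.with_values(plan.values * 0.9))
        rois = {"GTV": mask_from_bool(geom, np.ones((10, 10, 10), bool), "GTV")}
        df = course_report(plan, {1: daily}, daily, rois, n_fractions_plan=1)
        deltas = df["percent_delta"].to_numpy(dtype=float)
        deltas = deltas[~np.isnan(deltas)]
        assert deltas.size and np.all(deltas < 0.0)
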