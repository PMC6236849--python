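"""Stand-in dose engine, dose warping and accumulation."""

import datetime

import numpy as np
import pytest

from cbctdose.dose import (
    BeamSpec,
    DoseGrid,
    PlanChain,
    accumulate_4d,
    accumulate_course,
    beam_from_gantry,
    compute_dose,
    warp_dose,
)
from cbctdose.grids import Geometry, ScalarGrid, VectorField


@pytest.fixture
def slab():
    geom = Geometry((-59.0, -59.0, -59.0), (2.5, 2.5, 2.5), (48, 48, 48))
    return ScalarGrid(geom, np.zeros((48, 48, 48)), "HU")


@pytest.fixture
def si_beam():
    return BeamSpec(isocenter_mm=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
                    field_size_mm=(40.0, 40.0))


def make_dose(geom, values):
    return DoseGrid(ScalarGrid(geom, values, "Gy"))


class TestComputeDose:
    def test_exponential_depth_dose(self, slab, si_beam):
        # ln(dose) vs depth is linear with slope -mu after removing divergence
        dose = compute_dose(slab, [si_beam], step_mm=1.0)
        geom = slab.geometry
        z = geom.axis_coords(2)
        prof = dose.values[24, 24, :]
        dist = np.abs(z - si_beam.source_mm[2])
        attn = prof * (dist / si_beam.sad_mm) ** 2
        depth = z - z[0]
        coef = np.polyfit(depth, np.log(attn), 1)
        fitted = np.polyval(coef, depth)
        ss_res = np.sum((np.log(attn) - fitted) ** 2)
        ss_tot = np.sum((np.log(attn) - np.log(attn).mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.999
        assert coef[0] == pytest.approx(-si_beam.mu_per_mm, rel=0.02)

    def test_zero_weight_beams_give_zero_dose(self, slab):
        b = BeamSpec((0, 0, 0), (0, 0, 1), weight=0.0)
        dose = compute_dose(slab, [b])
        assert np.all(dose.values == 0.0)

    def test_parallel_opposed_symmetry(self, slab):
        up = BeamSpec((0, 0, 0), (0, 0, 1), field_size_mm=(40, 40))
        down = BeamSpec((0, 0, 0), (0, 0, -1), field_size_mm=(40, 40))
        dose = compute_dose(slab, [up, down], step_mm=1.0)
        prof = dose.values[24, 24, :]
        assert np.abs(prof - prof[::-1]).max() < 0.01 * prof.max()

    def test_source_inside_volume_rejected(self, slab):
        b = BeamSpec((0, 0, 0), (0, 0, 1), sad_mm=30.0)
        with pytest.raises(ValueError, match="source"):
            compute_dose(slab, [b])

    def test_empty_beam_list_rejected(self, slab):
        with pytest.raises(ValueError):
            compute_dose(slab, [])

    def test_gantry_beam_helper_directions(self):
        b0 = beam_from_gantry(0.0, (0, 0, 0))
        np.testing.assert_allclose(b0.direction, (0, 1, 0), atol=1e-12)
        b90 = beam_from_gantry(90.0, (0, 0, 0))
        np.testing.assert_allclose(b90.direction, (1, 0, 0), atol=1e-12)


class TestWarpDose:
    def test_identity_field_is_exact(self, slab, si_beam):
        dose = compute_dose(slab, [si_beam])
        warped = warp_dose(dose, VectorField.zeros(slab.geometry))
        assert np.array_equal(warped.values, dose.values)

    def test_translation_preserves_max(self, slab, si_beam):
        dose = compute_dose(slab, [si_beam], step_mm=1.0)
        f = VectorField.constant(slab.geometry, (5.0, 0.0, 0.0))
        warped = warp_dose(dose, f)
        assert warped.values.max() == pytest.approx(dose.values.max(), rel=0.01)

    def test_forward_then_inverse_round_trip(self, phantom32):
        from cbctdose.registration import invert_dvf

        geom = phantom32.ct4d.geometry
        pts = geom.voxel_centers()
        smooth = np.exp(-np.sum(pts ** 2, axis=-1) / (2 * 30.0 ** 2)) * 10.0
        dose = make_dose(geom, smooth)
        fwd = phantom32.gt_fields[5]
        back, stats = invert_dvf(fwd, tol_mm=0.05)
        round_trip = warp_dose(warp_dose(dose, fwd), back)
        interior = smooth > 1.0
        err = np.abs(round_trip.values - dose.values)[interior].max()
        assert err < 0.05 * smooth.max()

    def test_integral_dose_preserved_under_rigid_shift(self):
        # compact dose blob fully inside the grid, shifted rigidly
        geom = Geometry((-40, -40, -40), (2.0, 2.0, 2.0), (41, 41, 41))
        pts = geom.voxel_centers()
        blob = 10.0 * np.exp(-np.sum(pts ** 2, axis=-1) / (2 * 8.0 ** 2))
        dose = make_dose(geom, blob)
        f = VectorField.constant(geom, (3.0, -2.0, 5.0))
        warped = warp_dose(dose, f)
        assert warped.integral_dose() == pytest.approx(dose.integral_dose(),
                                                       rel=0.02)

    def test_non_negativity(self, phantom32, rng):
        geom = phantom32.ct4d.geometry
        dose = make_dose(geom, rng.uniform(0, 5, size=geom.size))
        warped = warp_dose(dose, phantom32.gt_fields[7])
        assert np.all(warped.values >= 0.0)


class TestAccumulate4D:
    def geom(self):
        return Geometry((0, 0, 0), (2, 2, 2), (12, 12, 12))

    def test_identical_doses_identity_fields(self, rng):
        geom = self.geom()
        d = make_dose(geom, rng.uniform(0, 10, size=(12, 12, 12)))
        out = accumulate_4d([d] * 10, [None] * 10)
        np.testing.assert_allclose(out.values, d.values, atol=1e-12)

    def test_single_hot_phase_linearity(self, rng):
        geom = self.geom()
        hot = make_dose(geom, rng.uniform(0, 10, size=(12, 12, 12)))
        zero = make_dose(geom, np.zeros((12, 12, 12)))
        out = accumulate_4d([hot] + [zero] * 9, [None] * 10)
        np.testing.assert_allclose(out.values, hot.values / 10.0, atol=1e-12)

    def test_weights_must_sum_to_one(self, rng):
        geom = self.geom()
        d = make_dose(geom, np.zeros((12, 12, 12)))
        with pytest.raises(ValueError, match="sum"):
            accumulate_4d([d] * 10, [None] * 10, weights=[0.2] * 10)

    def test_wrong_phase_count_rejected(self):
        geom = self.geom()
        d = make_dose(geom, np.zeros((12, 12, 12)))
        with pytest.raises(ValueError, match="10"):
            accumulate_4d([d] * 9, [None] * 9)

    def test_motion_compensation_beats_static_sum(self, phantom32):
        # accumulated GTV D99 with motion compensation >= blurred static sum
        from cbctdose.qa import dvh_metrics

        geom = phantom32.ct4d.geometry
        pts = geom.voxel_centers()
        doses = []
        for p in range(10):
            c = phantom32.spec.tumor_center_at_phase(p)
            vals = 10.0 * np.exp(-np.sum((pts - c) ** 2, axis=-1) / (2 * 12.0 ** 2))
            doses.append(make_dose(geom, vals))
        dvfs = [None] + [phantom32.gt_fields[p] for p in range(1, 10)]
        comp = accumulate_4d(doses, dvfs)
        static = accumulate_4d(doses, [None] * 10)
        gtv = phantom32.rois["GTV"]
        d99_comp = dvh_metrics(comp, gtv).d_gy[99]
        d99_static = dvh_metrics(static, gtv).d_gy[99]
        assert d99_comp >= d99_static


class TestAccumulateCourse:
    def geom(self):
        return Geometry((0, 0, 0), (2, 2, 2), (10, 10, 10))

    def chain(self):
        return PlanChain(plans=[("pretreatment", datetime.date(2024, 1, 1))])

    def test_identity_chain_sums_exactly(self, rng):
        geom = self.geom()
        daily = make_dose(geom, rng.uniform(0, 3, size=(10, 10, 10)))
        dated = [(datetime.date(2024, 1, 1 + k), daily) for k in range(4)]
        out = accumulate_course(dated, self.chain())
        np.testing.assert_allclose(out.values, 4.0 * daily.values, atol=1e-12)

    def test_single_fraction_equals_daily(self, rng):
        geom = self.geom()
        daily = make_dose(geom, rng.uniform(0, 3, size=(10, 10, 10)))
        out = accumulate_course([(datetime.date(2024, 1, 2), daily)], self.chain())
        np.testing.assert_allclose(out.values, daily.values, atol=1e-12)

    def test_replan_chain_composes_translations(self):
        # two-plan chain with translation links: net shift is the composition
        geom = Geometry((-40, -40, -40), (2.0, 2.0, 2.0), (41, 41, 41))
        pts = geom.voxel_centers()
        blob = 10.0 * np.exp(-np.sum(pts ** 2, axis=-1) / (2 * 8.0 ** 2))
        daily = make_dose(geom, blob)
        t1 = np.array([3.0, 0.0, 0.0])
        chain = PlanChain(
            plans=[("pretreatment", datetime.date(2024, 1, 1)),
                   ("replan1", datetime.date(2024, 1, 10))],
            links={1: VectorField.constant(geom, t1)},
        )
        out = accumulate_course([(datetime.date(2024, 1, 15), daily)], chain)
        # oracle: direct sampling of the blob at x + t1
        expected = 10.0 * np.exp(
            -np.sum((pts + t1) ** 2, axis=-1) / (2 * 8.0 ** 2))
        interior = expected > 0.5
        np.testing.assert_allclose(out.values[interior], expected[interior],
                                   rtol=0.02, atol=0.02)

    def test_fraction_before_first_plan_rejected(self, rng):
        geom = self.geom()
        daily = make_dose(geom, np.zeros((10, 10, 10)))
        with pytest.raises(ValueError, match="precede"):
            accumulate_course([(datetime.date(2023, 12, 31), daily)], self.chain())

    def test_chain_requires_increasing_dates(self):
        with pytest.raises(ValueError, match="increasing"):
            PlanChain(plans=[("a", datetime.date(2024, 1, 2)),
                             ("b", datetime.date(2024, 1, 1))])
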