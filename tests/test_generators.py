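"""Plan generators: MU arithmetic, geometry, and deliverability."""

import numpy as np
import pytest

from vmatqa import MachineLimits, validate_plan
from vmatqa.generators import (
    DEFAULT_DRGS_FACTORS,
    gen_dr_change_test,
    gen_dr_gs_strip_test,
    gen_mlc_speed_strip_test,
    gen_picket_fence,
    gen_reversal_test,
    gen_speed_limit_test,
    gen_utility_fields,
)


class TestSpeedLimitFields:
    @pytest.mark.parametrize("axis,travel,mu", [
        ("mlc", 10.0, 50.0),      # 10 cm * (10 MU/s) / 2 cm/s
        ("gantry", 180.0, 300.0),  # 180 deg * 10 / 6
        ("jaw", 10.0, 66.7),      # 10 * 10 / 1.5, quantised to 0.1 MU
    ])
    def test_sweep_relation_mu(self, limits, axis, travel, mu):
        plan = gen_speed_limit_test(axis, travel, limits)
        assert plan.total_mu == pytest.approx(mu, abs=0.051)

    def test_override_and_validation(self, limits):
        plan = gen_speed_limit_test("mlc", 10.0, limits, mu_override=49.0)
        assert plan.total_mu == pytest.approx(49.0)
        assert validate_plan(plan, limits) == []


class TestPicketFence:
    def test_layout(self, limits, fence_image):
        plan, _ = fence_image
        assert len(plan.strip_specs) == 7
        assert [s.x_start for s in plan.strip_specs] == [-9, -6, -3, 0, 3, 6, 9]
        assert validate_plan(plan, limits) == []

    def test_error_plan_differs_only_on_named_pairs(self, limits):
        clean = gen_picket_fence(limits, gap=0.6)
        err = gen_picket_fence(
            limits, errors=({"leaf_pair": 20, "widen_to": 0.15},
                            {"leaf_pair": 25, "shift": 0.05}))
        assert validate_plan(err, limits) == []
        a0 = np.stack([cp.bank_a for cp in clean.control_points])
        a1 = np.stack([cp.bank_a for cp in err.control_points])
        # error plans get more control points; compare per-pair trajectories
        # at common MU values instead
        mus0 = [cp.cum_mu for cp in clean.control_points]
        mus1 = [cp.cum_mu for cp in err.control_points]
        for pair in range(8, 32):
            t0 = np.interp(mus1, mus0, a0[:, pair])
            same = np.allclose(t0, a1[:, pair], atol=1e-9)
            assert same == (pair not in (20, 25))

    def test_error_gap_default_widens(self, limits):
        err = gen_picket_fence(limits, errors=({"leaf_pair": 20, "widen_to": 0.15},))
        assert "gap=0.6" in err.notes

    def test_empty_picket_list_is_plain_sweep(self, limits):
        plan = gen_picket_fence(limits, picket_positions=())
        # monotone bank trajectories, constant gap
        b = np.array([cp.bank_b[20] for cp in plan.control_points])
        a = np.array([cp.bank_a[20] for cp in plan.control_points])
        assert np.all(np.diff(b) >= 0) and np.allclose(b - a, 0.5)

    def test_rejects_tight_spacing(self, limits):
        with pytest.raises(ValueError):
            gen_picket_fence(limits, picket_positions=(0.0, 0.3))


class TestDrGsStrips:
    def test_inter_strip_move_mu(self, limits, drgs_bundle):
        plan, _, _ = drgs_bundle
        # move time 3 / (0.75*2) = 2 s at max/8 -> 2.5 MU
        assert "inter-strip MU=2.5" in plan.notes

    def test_matched_strips_share_arc_span(self, limits, drgs_bundle):
        plan, _, _ = drgs_bundle
        spans = [s.arc_span for s in plan.strip_specs if s.dr_factor == s.gs_factor]
        assert np.allclose(spans, 12.0)  # 20 MU * (6 f / 10 f) deg

    def test_total_mu_is_sum_of_parts(self, limits, drgs_bundle):
        plan, _, _ = drgs_bundle
        n = len(plan.strip_specs)
        expected = n * 20.0 + (n + 1) * 2.5  # strips + moves incl. lead-in/out
        assert plan.total_mu == pytest.approx(expected)

    def test_validates_clean(self, limits, drgs_bundle):
        assert validate_plan(drgs_bundle[0], limits) == []

    def test_arc_budget_enforced(self, limits):
        with pytest.raises(ValueError):
            gen_dr_gs_strip_test(limits, mu_strip=70.0)


class TestMlcSpeedStrips:
    def test_strip_mu_from_sweep_relation(self, limits, mlc_speed_bundle):
        plan, _, _ = mlc_speed_bundle
        # sweep relation: 3 cm * 10 (MU/s) / 2 (cm/s) = 15 MU per strip
        assert all(s.planned_mu == pytest.approx(15.0) for s in plan.strip_specs)

    def test_gantry_speed_from_mu_floor(self, limits, mlc_speed_bundle):
        plan, _, _ = mlc_speed_bundle
        assert "GS 3.125 deg/s" in plan.notes  # (18.75/60)/0.1

    def test_small_gap_rejected(self, limits):
        with pytest.raises(ValueError):
            gen_mlc_speed_strip_test(limits, gap=0.4)

    def test_validates_clean(self, limits, mlc_speed_bundle):
        assert validate_plan(mlc_speed_bundle[0], limits) == []


class TestReversal:
    def test_one_plan_per_speed_factor(self, limits, reversal_plans):
        assert len(reversal_plans) == 4
        assert reversal_plans[-1].notes.startswith("reversal strips, leaf speed 0.36")

    def test_strip_metadata(self, reversal_plans):
        plan = reversal_plans[0]
        assert [s.x_end for s in plan.strip_specs] == [-5.6, -1.6, 3.6, 7.6, 10.6]
        assert [s.traversal_count for s in plan.strip_specs] == [1, 3, 5, 7, 5.5]
        # per-traversal fluence closed form at full speed: 0.8 cm / 2 cm/s * 5 MU/s
        assert plan.strip_specs[0].planned_mu == pytest.approx(2.0)

    def test_validates_clean(self, limits, reversal_plans):
        for plan in reversal_plans:
            assert validate_plan(plan, limits) == []


class TestDrChange:
    def test_dr_sequences(self, limits):
        inc, ref = gen_dr_change_test("increase", limits)
        seq = [s.dr_factor for s in inc.strip_specs]
        assert seq == [1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 1 / 32, 1.0]
        dec, _ = gen_dr_change_test("decrease", limits)
        assert [s.dr_factor for s in dec.strip_specs] == seq[::-1]
        # reference differs only in leaf speed
        assert ref.strip_specs[0].mlc_speed_factor == pytest.approx(0.125)
        assert validate_plan(inc, limits) == []
        assert validate_plan(ref, limits) == []

    def test_gantry_speed(self, limits):
        inc, _ = gen_dr_change_test("increase", limits)
        assert "GS 3.125 deg/s" in inc.notes

    def test_unknown_direction(self, limits):
        with pytest.raises(ValueError):
            gen_dr_change_test("sideways", limits)


class TestUtilityFields:
    def test_gravity_gantry_speed(self, limits):
        plan = gen_utility_fields("dmlc_gravity", limits)
        assert "arc GS 5.79 deg/s" in plan.notes
        assert plan.total_mu == pytest.approx(600 / 60 * 23 / 0.74, abs=0.051)
        assert validate_plan(plan, limits) == []

    def test_static_and_arc_mu(self, limits):
        static = gen_utility_fields("static_mu", limits, mu=36.0)
        assert static.total_mu == 36.0
        arc = gen_utility_fields("arc_mu", limits, mu=1000.0)
        # 1000 MU over 360 deg: 2.78 MU/deg, gantry well under its maximum
        assert arc.total_mu / 360.0 == pytest.approx(2.78, abs=0.005)
        assert validate_plan(arc, limits) == []
        arc36 = gen_utility_fields("arc_mu", limits, mu=36.0)
        assert validate_plan(arc36, limits) == []  # exactly at the MU/deg floor

    def test_unknown_kind(self, limits):
        with pytest.raises(ValueError):
            gen_utility_fields("wedge", limits)


def test_default_factor_tables():
    assert DEFAULT_DRGS_FACTORS[-2:] == ((1.2, 1.0), (1.0, 1.2))
    assert len(DEFAULT_DRGS_FACTORS) == 8
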