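"""Delivery simulation: timing, bin selection, capping, MU conservation,
fluence rendering against closed forms, and error injection."""

import numpy as np
import pytest

from vmatqa import (
    DetectorModel,
    ErrorModel,
    MachineLimits,
    render_fluence,
    sample_detector,
    simulate,
)
from vmatqa.generators import (
    gen_dr_gs_strip_test,
    gen_picket_fence,
    gen_speed_limit_test,
    gen_utility_fields,
)


class TestSimulate:
    def test_sweep_durations_follow_bin_choice(self, limits):
        # 50 MU runs the 10 cm sweep at the top bin: 5.0 s
        tr = simulate(gen_speed_limit_test("mlc", 10.0, limits), limits)
        assert tr.duration == pytest.approx(5.0)
        assert tr.active_bin.max() == 0
        # 49 MU forces half-maximum: 9.8 s
        tr = simulate(gen_speed_limit_test("mlc", 10.0, limits, mu_override=49.0),
                      limits)
        assert tr.duration == pytest.approx(9.8)
        assert tr.active_bin[len(tr.active_bin) // 2] == 1

    def test_static_field_duration(self, limits):
        plan = gen_utility_fields("open_field", limits, mu=100.0)
        tr = simulate(plan, limits)
        assert tr.duration == pytest.approx(10.0)
        assert np.all(np.diff(tr.cum_mu) >= 0)

    def test_mu_conserved_everywhere(self, limits):
        for plan in (gen_speed_limit_test("mlc", 10.0, limits),
                     gen_dr_gs_strip_test(limits),
                     gen_picket_fence(limits)):
            tr = simulate(plan, limits)
            assert tr.total_mu == pytest.approx(plan.total_mu, abs=1e-9)

    def test_leaf_speed_never_exceeds_limit(self, limits, fence_image):
        plan, _ = fence_image
        tr = simulate(plan, limits)
        dt = np.diff(tr.t)
        ok = dt > 1e-12
        v = np.abs(np.diff(tr.bank_b[:, 20])[ok]) / dt[ok]
        assert v.max() <= limits.mlc_speed_max * (1 + 1e-6)

    def test_over_maximum_strip_capped_but_delivered(self, limits):
        """The 1.2x DR strip delivers its full MU at the capped rate."""
        plan = gen_dr_gs_strip_test(limits)
        tr = simulate(plan, limits)
        assert tr.total_mu == pytest.approx(plan.total_mu, abs=1e-9)
        assert tr.rate.max() <= limits.dr_max_mu_s * (1 + 1e-9)
        assert any(e["kind"] == "cap" for e in tr.events)

    def test_dt_validation(self, limits):
        with pytest.raises(ValueError):
            simulate(gen_speed_limit_test("mlc", 10.0, limits), limits, dt=0.0)


class TestRenderFluence:
    def test_static_field_exact(self, limits, detector, open_field_image):
        img = open_field_image(100.0)
        i = np.argmin(np.abs(img.x))
        j = np.argmin(np.abs(img.y))
        assert img.data[j, i] == pytest.approx(100.0, abs=1e-6)
        # far outside the field
        assert img.data[j, 2] == pytest.approx(0.0, abs=1e-9)

    def test_gravity_sweep_matches_closed_form(self, limits, detector):
        """Uniform sweep: fluence = DR * gap / speed = 13.51 MU-units."""
        plan = gen_utility_fields("dmlc_gravity", limits)
        img = render_fluence(simulate(plan, limits), detector)
        i = np.argmin(np.abs(img.x))
        j = np.argmin(np.abs(img.y))
        expected = limits.dr_max_mu_s * 1.0 / 0.74
        assert img.data[j, i] == pytest.approx(expected, rel=5e-3)

    def test_render_deterministic_without_noise(self, limits, detector):
        plan = gen_utility_fields("open_field", limits, mu=10.0)
        tr = simulate(plan, limits)
        a = render_fluence(tr, detector, seed=1)
        b = render_fluence(tr, detector, seed=2)
        assert np.array_equal(a.data, b.data)

    def test_noise_and_pixilation_are_seeded(self, limits, detector):
        plan = gen_utility_fields("open_field", limits, mu=10.0)
        tr = simulate(plan, limits)
        err = ErrorModel(noise_sigma=0.02, pixilation_lines=((500, 0.1),))
        a = render_fluence(tr, detector, err, seed=7)
        b = render_fluence(tr, detector, err, seed=7)
        c = render_fluence(tr, detector, err, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        # the pixilation column is boosted in both
        j = np.argmin(np.abs(a.y))
        assert a.data[j, 500] > 1.05 * a.data[j, 499]

    def test_leaf_offset_shifts_field_edge(self, limits, detector):
        plan = gen_utility_fields("open_field", limits, mu=10.0)
        tr0 = simulate(plan, limits)
        tr1 = simulate(plan, limits, ErrorModel(leaf_offset=0.5))
        a = render_fluence(tr0, detector)
        b = render_fluence(tr1, detector)
        j = np.argmin(np.abs(a.y))
        # at the nominal left edge (-12.5): offset +0.5 closes that pixel
        i = np.argmin(np.abs(a.x + 12.4))
        assert a.data[j, i] > 0.9 * 10 and b.data[j, i] < 0.1 * 10


class TestSampleDetector:
    def test_uniform_readings(self, limits, open_field_image):
        img = open_field_image(50.0)
        det = DetectorModel()
        pts = [(x, 0.5) for x in np.linspace(-5.5, 5.5, 12)]
        vals = sample_detector(img, det, pts)
        assert np.allclose(vals, 50.0, atol=1e-6)

    def test_diode_mode_averages(self, limits, open_field_image):
        img = open_field_image(50.0)
        det = DetectorModel(kind="diode_array", pixel_pitch=0.256)
        vals = sample_detector(img, det, [(0.0, 0.0)])
        assert vals[0] == pytest.approx(50.0, abs=1e-6)

    def test_point_outside_rejected(self, limits, open_field_image):
        img = open_field_image(10.0)
        with pytest.raises(ValueError):
            sample_detector(img, DetectorModel(), [(99.0, 0.0)])

    def test_linear_ramp_midpoint(self):
        # synthetic ramp image: nearest-pixel readout returns midpoint value
        from vmatqa.simulator import FluenceImage
        x = np.linspace(-1, 1, 201)
        y = np.linspace(-1, 1, 5)
        data = np.tile(50.0 * (x + 1.0), (len(y), 1))
        img = FluenceImage(data=data, x=x, y=y)
        v = sample_detector(img, DetectorModel(), [(0.0, 0.0)])
        assert v[0] == pytest.approx(50.0, abs=0.5)


class TestPicketAccuracy:
    def test_noiseless_peaks_within_half_pixel(self, fence_image, fence_image_static):
        from vmatqa.analysis import find_picket_peaks
        for plan, img in (fence_image, fence_image_static):
            peaks, ties = find_picket_peaks(img, 7)
            width = plan.strip_specs[0].width
            nominal = np.array([s.x_start for s in plan.strip_specs]) + width / 2
            assert np.max(np.abs(peaks - nominal)) <= 0.5 * 0.0256
            assert not any(ties)
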