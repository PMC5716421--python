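"""Analysis operations: smoothing, despiking, normalisation, strip stats,
picket aggregation/error detection, junction analyses, chamber reports.

Printed-table fixtures reproduce the derived cells of the published
commissioning session (imager centres, chamber readings, picket peaks)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vmatqa.analysis import (
    aggregate_pickets,
    center_pixel_report,
    chamber_report,
    despike_pair,
    detect_picket_errors,
    moving_average,
    normalize_to_open,
    profile_dr_compare,
    smoothing_window_mm,
    strip_stats,
)
from vmatqa.simulator import DetectorModel, FluenceImage


class TestMovingAverage:
    def test_window_widths_at_epid_pitch(self):
        assert smoothing_window_mm(7, 0.256) == pytest.approx(1.8, abs=0.01)
        assert smoothing_window_mm(3, 0.256) == pytest.approx(0.77, abs=0.005)

    def test_constant_profile_unchanged(self):
        p = np.full(50, 7.0)
        assert np.allclose(moving_average(p, 7), 7.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 100), min_size=9, max_size=60),
           st.sampled_from([3, 5, 7]))
    def test_commutes_with_reversal_and_preserves_mean(self, vals, n):
        p = np.asarray(vals)
        sm = moving_average(p, n)
        assert np.allclose(moving_average(p[::-1], n), sm[::-1])
        # interior windows are plain means: check one explicitly
        i = len(p) // 2
        assert sm[i] == pytest.approx(p[i - n // 2:i + n // 2 + 1].mean())


class TestDespike:
    def test_clean_profiles_average(self):
        a = np.linspace(10, 12, 40)
        b = a + 0.02
        out = despike_pair(a, b, spacing_mm=0.256)
        assert np.allclose(out, a + 0.01)

    def test_single_column_spike_removed(self):
        rng = np.random.default_rng(0)
        a = np.full(60, 100.0)
        b = np.full(60, 100.0)
        a[30] *= 1.10  # +10% pixilation line in one repeat
        out = despike_pair(a, b, spacing_mm=0.256)
        assert out[30] == pytest.approx(100.0)
        clean = np.ones(60, bool)
        clean[30] = False
        assert np.allclose(out[clean], 100.0)

    def test_double_spike_marked_missing(self):
        a = np.full(60, 100.0)
        b = np.full(60, 100.0)
        a[30] *= 1.2
        b[30] *= 1.2
        out = despike_pair(a, b, spacing_mm=0.256)
        assert np.isnan(out[30])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            despike_pair(np.ones(5), np.ones(6), 0.256)


def _flat_image(value, n=101, span=10.0):
    x = np.linspace(-span, span, n)
    y = np.linspace(-span, span, n)
    return FluenceImage(data=np.full((n, n), float(value)), x=x, y=y)


class TestNormalize:
    def test_identity_and_scaling(self):
        open_ref = _flat_image(8.0)
        assert np.allclose(normalize_to_open(open_ref, open_ref).data, 100.0)
        test = _flat_image(8.16)
        assert np.allclose(normalize_to_open(test, open_ref).data, 102.0)

    def test_floor_masked(self):
        open_ref = _flat_image(8.0)
        open_ref.data[:, :10] = 0.01  # below 5% floor
        out = normalize_to_open(_flat_image(8.0), open_ref)
        assert np.isnan(out.data[:, :10]).all()
        assert np.allclose(out.data[:, 20:], 100.0)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_open(_flat_image(1.0, n=50), _flat_image(1.0, n=60))


class TestStripStats:
    def test_uniform_image(self):
        from vmatqa.machine import StripSpec
        img = _flat_image(95.0, n=201, span=13.0)
        strips = [StripSpec(index=i, x_start=-12 + 3 * i, x_end=-9 + 3 * i)
                  for i in range(8)]
        rep = strip_stats(img, strips, DetectorModel(kind="diode_array"))
        assert np.allclose(rep.means(), 95.0)
        assert all(r["sd_pct"] == pytest.approx(0.0, abs=1e-9) for r in rep.rows)
        assert all(r["n_samples"] == 12 for r in rep.rows)


class TestProfileDrCompare:
    def test_identical_and_scaled(self):
        x = np.linspace(-14, 14, 281)
        base = np.where(np.abs(x) < 12.5, 100.0, 1.0)
        out = profile_dr_compare({0: base, 3: base, 5: 1.02 * base}, x)
        assert out[3]["max_deviation_pct"] == pytest.approx(0.0, abs=1e-9)
        assert out[5]["max_deviation_pct"] == pytest.approx(2.0)
        assert out[0]["flatness_pct"] == pytest.approx(0.0, abs=1e-9)
        assert out[0]["symmetry_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_simulated_open_fields_dr_independent(self, limits, detector,
                                                  open_field_image):
        """The ideal delivery gives identical profiles at every DR bin."""
        from vmatqa import render_fluence, simulate
        from vmatqa.generators import gen_utility_fields
        profs = {}
        for k in (0, 3, 5):
            plan = gen_utility_fields("open_field", limits, mu=20.0, dr_bin=k)
            img = render_fluence(simulate(plan, limits), detector)
            profs[k] = img.profile((0.25, 0.75))
        out = profile_dr_compare(profs, img.x, reference_bin=0)
        assert all(v["max_deviation_pct"] < 0.1 for v in out.values())


TABLE5_PEAKS = {
    270: [-9.16, -6.06, -3.01, 0.06, 3.11, 6.16, 9.20],
    180: [-9.06, -5.98, -2.94, 0.14, 3.16, 6.21, 9.25],
    90: [-9.08, -5.96, -2.94, 0.14, 3.19, 6.26, 9.31],
    0: [-9.16, -6.06, -2.99, 0.06, 3.13, 6.21, 9.25],
    "arc": [-9.08, -5.98, -2.91, 0.19, 3.21, 6.31, 9.36],
}


class TestAggregatePickets:
    def test_published_static_aggregates(self):
        rep = aggregate_pickets(TABLE5_PEAKS)
        # row 4 (central picket): mean 0.10, range 0.08; row 1: mean -9.115
        assert rep.static_average[3] == pytest.approx(0.10)
        assert rep.static_average[0] == pytest.approx(-9.115)
        assert rep.static_range[3] == pytest.approx(0.08)
        # arc - static mean for the central picket: 0.19 - 0.10 = +0.09
        assert rep.arc_minus_average[3] == pytest.approx(0.09)

    def test_identical_acquisitions_collapse(self):
        peaks = {0: [1.0, 2.0], 90: [1.0, 2.0], "arc": [1.0, 2.0]}
        rep = aggregate_pickets(peaks)
        assert rep.static_range == [0.0, 0.0]
        assert rep.arc_minus_average == [0.0, 0.0]

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pickets({0: [1.0], 90: [1.0, 2.0]})

    def test_single_static_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pickets({0: [1.0], "arc": [1.0]})


class TestDetectPicketErrors:
    def test_flags_and_magnitudes(self):
        nominal = [0.05, 3.05]
        centers = {5: [0.05, 3.05], 6: [0.10, 3.10]}
        widths = {5: [0.10, 0.10], 6: [0.10, 0.10]}
        flags = detect_picket_errors(centers, widths, nominal, 0.10)
        assert {f["leaf_pair"] for f in flags} == {6}
        assert all(f["kind"] == "shift" for f in flags)
        assert flags[0]["deviation"] == pytest.approx(0.05)

    def test_clean_input_no_flags(self):
        flags = detect_picket_errors({5: [0.05]}, {5: [0.10]}, [0.05], 0.10)
        assert flags == []


class TestChamberReport:
    def test_published_6mv_readings(self):
        """Monitor-chamber stability table: arc/static 0.994 and 1.001."""
        rep = chamber_report(
            static_readings={36: 6.361, 1000: 176.70},
            arc_readings={36: {"CW": 6.325, "CCW": 6.324},
                          1000: {"CW": 176.94, "CCW": 176.82}},
        )
        assert rep.arc_static_ratio[36] == pytest.approx(0.994, abs=5e-4)
        assert rep.arc_static_ratio[1000] == pytest.approx(1.001, abs=5e-4)
        assert rep.linearity_deviation <= 0.003  # within 0.3%

    def test_published_dmlc_gravity_readings(self):
        rep = chamber_report(
            static_readings={36: 1.0},
            arc_readings={},
            dmlc_readings={0: 2.09, 90: 2.08, 180: 2.09, 270: 2.09, "arc": 2.08},
        )
        assert rep.dmlc_ratios["arc"] == pytest.approx(0.996, abs=5e-4)
        assert rep.dmlc_ratios[90] == pytest.approx(0.996, abs=5e-4)
        assert all(abs(r - 1) <= 0.005 for r in rep.dmlc_ratios.values())

    def test_identical_readings(self):
        rep = chamber_report(
            static_readings={36: 2.0, 1000: 2.0 * 1000 / 36},
            arc_readings={36: [2.0, 2.0]},
        )
        assert rep.arc_static_ratio[36] == pytest.approx(1.0)
        assert rep.linearity_deviation == pytest.approx(0.0, abs=1e-12)

    def test_missing_static_rejected(self):
        with pytest.raises(ValueError):
            chamber_report({}, {36: [1.0]})


class TestCenterPixelReport:
    def test_published_imager_centres(self):
        centres = {180: (13.06, 13.37), 90: (13.06, 13.27),
                   270: (13.04, 13.27), 0: (13.06, 13.16)}
        rep = center_pixel_report(centres)
        assert rep["deviation_cm"][270][0] == pytest.approx(-0.015)
        assert rep["mean_y_cm"] == pytest.approx(13.2675)
        assert rep["deviation_cm"][180][1] == pytest.approx(0.1025, abs=5e-4)

    def test_identical_centres(self):
        rep = center_pixel_report({0: (1.0, 2.0), 90: (1.0, 2.0)})
        assert rep["deviation_cm"][0] == (0.0, 0.0)

    def test_single_angle_rejected(self):
        with pytest.raises(ValueError):
            center_pixel_report({0: (1.0, 2.0)})
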