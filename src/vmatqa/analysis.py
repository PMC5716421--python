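"""Measurement analyses for the commissioning tests.

All profile work happens on cross-plane 1-D profiles (the leaf-travel
direction) extracted from :class:`~vmatqa.simulator.FluenceImage` grids or
supplied directly.  Percentages follow the conventions of portal-image QA:
normalised doses are in percent of the reference, peak positions and widths
in cm unless a function documents mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulator import DetectorModel, FluenceImage, sample_detector

__all__ = [
    "PicketReport",
    "StripReport",
    "TransitionReport",
    "ReversalReport",
    "ChamberReport",
    "find_picket_peaks",
    "picket_metrics",
    "analyze_picket_image",
    "aggregate_pickets",
    "detect_picket_errors",
    "moving_average",
    "smoothing_window_mm",
    "despike_pair",
    "normalize_to_open",
    "strip_stats",
    "profile_dr_compare",
    "reversal_analysis",
    "transition_analysis",
    "chamber_report",
    "center_pixel_report",
]


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass
class PicketReport:
    """Per-picket peak statistics over repeated acquisitions."""

    nominal: list
    peaks_by_acquisition: dict
    static_range: list
    static_average: list
    arc_minus_average: list

    def to_dict(self) -> dict:
        return {
            "nominal_cm": self.nominal,
            "peaks_by_acquisition_cm": self.peaks_by_acquisition,
            "static_range_cm": self.static_range,
            "static_average_cm": self.static_average,
            "arc_minus_average_cm": self.arc_minus_average,
        }


@dataclass
class StripReport:
    """Mean +/- SD of normalised dose per strip."""

    rows: list  # dicts: index, mean_pct, sd_pct, n_samples, factors

    def means(self) -> np.ndarray:
        return np.array([r["mean_pct"] for r in self.rows])


@dataclass
class TransitionReport:
    rows: list  # dicts: junction_cm, max_excursion_pct, width_2pct_mm, width_3pct_mm


@dataclass
class ReversalReport:
    rows: list            # per junction: overdose_pct, underdose_pct, excess_area, ...
    rate_pct_per_reversal: float = float("nan")


@dataclass
class ChamberReport:
    arc_static_ratio: dict
    linearity_deviation: float
    dmlc_ratios: dict


# ---------------------------------------------------------------------------
# picket fence
# ---------------------------------------------------------------------------

def find_picket_peaks(
    image: FluenceImage,
    n_expected: int,
    y_band: Sequence[float] = (-0.5, 0.5),
) -> tuple:
    """Locate picket peaks as local-maximum pixel centres.

    Returns ``(positions_cm, tie_flags)``.  Within each picket's window a
    non-unique maximum is flagged and broken toward smaller cross-plane
    coordinate rather than silently resolved.
    """
    prof = image.profile(y_band)
    x = image.x
    spacing_px = max(int(len(x) / (n_expected + 1) / 2), 2)
    idx, _ = find_peaks(prof, distance=spacing_px,
                        prominence=0.05 * (prof.max() - prof.min() + 1e-30))
    if len(idx) < n_expected:
        raise ValueError(f"found {len(idx)} pickets, expected {n_expected}")
    # keep the n strongest, in spatial order
    strongest = np.sort(idx[np.argsort(prof[idx])[-n_expected:]])
    positions, ties = [], []
    half_win = max(spacing_px // 2, 2)
    for i in strongest:
        lo, hi = max(i - half_win, 0), min(i + half_win + 1, len(prof))
        seg = prof[lo:hi]
        m = seg.max()
        at = np.nonzero(seg == m)[0]
        ties.append(len(at) > 1)
        positions.append(float(x[lo + at[0]]))
    return np.array(positions), ties


def picket_metrics(
    profile: np.ndarray,
    x: np.ndarray,
    nominal_positions: Sequence[float],
    window: float = 1.0,
) -> list:
    """Sub-pixel centre and width of each picket from half-prominence edges.

    The picket sits on the uniform sweep baseline; the baseline is estimated
    from the outer quarter of the search window, and the strip edges are the
    interpolated crossings of the half-prominence level.  Returns dicts with
    ``center``, ``width`` (cm) and ``peak`` value.
    """
    out = []
    for p in nominal_positions:
        sel = np.nonzero((x >= p - window) & (x <= p + window))[0]
        seg, xs = profile[sel], x[sel]
        edge = max(len(seg) // 4, 1)
        base = np.median(np.concatenate([seg[:edge], seg[-edge:]]))
        i_pk = int(np.argmax(seg))
        half = 0.5 * (base + seg[i_pk])

        def cross(i0, step):
            i = i_pk
            while 0 < i < len(seg) - 1 and seg[i + step] >= half:
                i += step
            j = i + step
            if not (0 <= j < len(seg)) or seg[j] == seg[i]:
                return xs[i]
            f = (half - seg[i]) / (seg[j] - seg[i])
            return xs[i] + f * (xs[j] - xs[i])

        xl = cross(i_pk, -1)
        xr = cross(i_pk, +1)
        out.append({"center": float(0.5 * (xl + xr)),
                    "width": float(xr - xl),
                    "peak": float(seg[i_pk]),
                    "baseline": float(base)})
    return out


def analyze_picket_image(
    image: FluenceImage,
    nominal_positions: Sequence[float],
    pairs: Sequence[int],
    margin: float = 0.2,
) -> tuple:
    """Per-leaf-pair picket centres and widths from a fence image.

    For each leaf pair the cross-plane profile is averaged over the central
    part of the pair's 1 cm band (``margin`` cm trimmed at each side to avoid
    crosstalk from neighbouring pairs) and each picket is measured with
    :func:`picket_metrics`.  Returns ``(centers_by_pair, widths_by_pair)``.
    """
    centers, widths = {}, {}
    for pair in pairs:
        lo = pair - 20.0 + margin
        hi = pair - 19.0 - margin
        prof = image.profile((lo, hi))
        mets = picket_metrics(prof, image.x, nominal_positions)
        centers[pair] = [m["center"] for m in mets]
        widths[pair] = [m["width"] for m in mets]
    return centers, widths


def aggregate_pickets(peaks_by_acquisition: dict, arc_label: str = "arc") -> PicketReport:
    """Range/mean of static-gantry peaks and the arc-vs-static difference."""
    statics = {k: np.asarray(v, dtype=float)
               for k, v in peaks_by_acquisition.items() if k != arc_label}
    if len(statics) < 2:
        raise ValueError("need at least two static acquisitions")
    lengths = {len(v) for v in peaks_by_acquisition.values()}
    if len(lengths) != 1:
        raise ValueError("mismatched picket counts between acquisitions")
    stat = np.stack(list(statics.values()))
    mean = stat.mean(axis=0)
    rng = stat.max(axis=0) - stat.min(axis=0)
    arc = np.asarray(peaks_by_acquisition.get(arc_label, mean), dtype=float)
    return PicketReport(
        nominal=[],
        peaks_by_acquisition={k: np.asarray(v).tolist()
                              for k, v in peaks_by_acquisition.items()},
        static_range=rng.tolist(),
        static_average=mean.tolist(),
        arc_minus_average=(arc - mean).tolist(),
    )


def detect_picket_errors(
    centers_by_pair: dict,
    widths_by_pair: dict,
    nominal_centers: Sequence[float],
    nominal_width: float,
    tol: float = 0.05,
    resolution: float = 0.0128,
) -> list:
    """Flag leaf pairs whose strip width or position deviates >= ``tol`` cm.

    ``centers_by_pair``/``widths_by_pair`` map leaf-pair index to per-picket
    measured centres and widths.  ``resolution`` (default half an EPID pixel)
    is credited to the comparison so that a deviation at exactly the
    tolerance is not missed through measurement granularity.  Returns flag
    dicts carrying the signed deviation; an empty list means no pair differs
    from nominal.
    """
    flags = []
    thr = tol - resolution
    for pair, centers in centers_by_pair.items():
        widths = widths_by_pair[pair]
        for k, (c, w) in enumerate(zip(centers, widths)):
            dw = w - nominal_width
            dc = c - nominal_centers[k]
            if abs(dw) >= thr:
                flags.append({"leaf_pair": pair, "picket": k, "kind": "width",
                              "measured": float(w), "deviation": float(dw)})
            if abs(dc) >= thr:
                flags.append({"leaf_pair": pair, "picket": k, "kind": "shift",
                              "measured": float(c), "deviation": float(dc)})
    return flags


# ---------------------------------------------------------------------------
# profile conditioning
# ---------------------------------------------------------------------------

def moving_average(profile: np.ndarray, n: int) -> np.ndarray:
    """Centred n-sample moving average; edges use the truncated window."""
    if n % 2 == 0 or n < 1:
        raise ValueError("n must be odd and >= 1")
    prof = np.asarray(profile, dtype=float)
    half = n // 2
    c = np.concatenate([[0.0], np.cumsum(prof)])
    i = np.arange(len(prof))
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, len(prof) - 1)
    return (c[hi + 1] - c[lo]) / (hi + 1 - lo)


def smoothing_window_mm(n: int, spacing_mm: float) -> float:
    """Physical width of an n-sample window (e.g. 7 px at 0.256 mm = 1.8 mm)."""
    return n * spacing_mm


def despike_pair(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    spacing_mm: float,
    threshold: float = 0.03,
    window_mm: float = 0.5,
) -> np.ndarray:
    """Average two repeat profiles, dropping single-column pixilation spikes.

    A sample is a spike when it deviates more than ``threshold`` (fractional)
    from its own profile's values ``window_mm`` to either side.  Spiked
    samples are excluded from the average; a position spiked in both repeats
    is returned as NaN (missing).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must be aligned and equal length")
    k = max(int(round(window_mm / spacing_mm)), 1)

    def spikes(p):
        left = np.roll(p, k)
        right = np.roll(p, -k)
        left[:k] = p[:k]
        right[-k:] = p[-k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            dl = np.abs(p - left) / np.where(left != 0, np.abs(left), 1.0)
            dr = np.abs(p - right) / np.where(right != 0, np.abs(right), 1.0)
        return (dl > threshold) & (dr > threshold)

    sa, sb = spikes(a), spikes(b)
    out = np.where(sa & ~sb, b, np.where(sb & ~sa, a, 0.5 * (a + b)))
    out[sa & sb] = np.nan
    return out


def normalize_to_open(
    test: FluenceImage,
    open_ref: FluenceImage,
    floor_frac: float = 0.05,
) -> FluenceImage:
    """Pointwise 100*test/open (%), masking pixels below the open-field floor."""
    if test.data.shape != open_ref.data.shape or not np.allclose(test.x, open_ref.x):
        raise ValueError("test and reference images have different geometry")
    floor = floor_frac * np.nanmax(open_ref.data)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 100.0 * test.data / open_ref.data
    ratio[open_ref.data <= floor] = np.nan
    return FluenceImage(data=ratio, x=test.x.copy(), y=test.y.copy(),
                        provenance={**test.provenance, "normalized_to": "open_field"})


# ---------------------------------------------------------------------------
# strip statistics
# ---------------------------------------------------------------------------

def strip_stats(
    normalized: FluenceImage,
    strips: Sequence,
    detector: DetectorModel,
    strip_length: float = 11.0,
    n_diodes: int = 12,
    epid_band: Sequence[float] = (0.25, 0.75),
    epid_smooth_px: int = 7,
) -> StripReport:
    """Mean +/- SD of normalised dose per strip.

    Diode mode samples ``n_diodes`` points at 1 cm spacing across the central
    ``strip_length`` of each strip at mid-strip.  EPID mode takes the
    smoothed midpoint of a cross-plane profile averaged over a half-leaf
    transverse band, with the SD of the raw pixels inside the smoothing
    window.
    """
    rows = []
    for s in strips:
        factors = {"dr_factor": s.dr_factor, "gs_factor": s.gs_factor,
                   "mlc_speed_factor": s.mlc_speed_factor}
        if detector.kind == "diode_array":
            ys = (np.arange(n_diodes) - (n_diodes - 1) / 2.0) * (
                strip_length / (n_diodes - 1))
            pts = [(s.x_mid, yy) for yy in ys]
            vals = sample_detector(normalized, detector, pts)
            rows.append({"index": s.index, "mean_pct": float(np.nanmean(vals)),
                         "sd_pct": float(np.nanstd(vals, ddof=1)),
                         "n_samples": int(len(vals)), **factors})
        else:
            prof = normalized.profile(epid_band)
            sm = moving_average(np.nan_to_num(prof, nan=np.nanmedian(prof)),
                                epid_smooth_px)
            i = int(np.argmin(np.abs(normalized.x - s.x_mid)))
            h = epid_smooth_px // 2
            raw = prof[max(i - h, 0):i + h + 1]
            rows.append({"index": s.index, "mean_pct": float(sm[i]),
                         "sd_pct": float(np.nanstd(raw, ddof=1)),
                         "n_samples": int(len(raw)), **factors})
    return StripReport(rows=rows)


def profile_dr_compare(
    profiles: dict,
    x: np.ndarray,
    reference_bin: int = 0,
) -> dict:
    """Compare open-field profiles across dose-rate bins.

    Deviation is the pointwise percent difference from the reference bin over
    the central 80% of the field (field = where the reference exceeds half
    its maximum).  Flatness is 100*(max-min)/(max+min) over the same region;
    symmetry is the maximum point-vs-mirror difference in percent.
    """
    ref = np.asarray(profiles[reference_bin], dtype=float)
    infield = np.nonzero(ref > 0.5 * np.nanmax(ref))[0]
    lo_x, hi_x = x[infield[0]], x[infield[-1]]
    c, hw = 0.5 * (lo_x + hi_x), 0.4 * (hi_x - lo_x)
    central = (x >= c - hw) & (x <= c + hw)
    out = {}
    for k, prof in profiles.items():
        p = np.asarray(prof, dtype=float)
        dev = 100.0 * np.nanmax(np.abs(p[central] - ref[central]) / ref[central])
        seg = p[central]
        flat = 100.0 * (np.nanmax(seg) - np.nanmin(seg)) / (np.nanmax(seg) + np.nanmin(seg))
        sym = 100.0 * np.nanmax(np.abs(seg - seg[::-1]) / seg)
        out[k] = {"max_deviation_pct": float(dev), "flatness_pct": float(flat),
                  "symmetry_pct": float(sym)}
    return out


# ---------------------------------------------------------------------------
# reversal and dose-rate-change junctions
# ---------------------------------------------------------------------------

def junction_turn_balance(plan, junctions: Sequence[float], pair: int = 20,
                          tol: float = 1e-6) -> list:
    """Net signed leading-edge reversal count at each junction of a plan.

    A reversal whose apex is a local maximum of the leading (bank B) edge
    counts +1 (its over-travel excursion adds fluence beyond the junction), a
    local minimum counts -1 (it removes fluence); opposite-sign reversals at
    the same junction cancel in the delivered fluence.
    """
    xb = np.array([cp.bank_b[pair] for cp in plan.control_points])
    net = []
    for jn in junctions:
        n = 0
        for i in range(1, len(xb) - 1):
            if abs(xb[i] - jn) <= tol:
                s_in = xb[i] - xb[i - 1]
                s_out = xb[i + 1] - xb[i]
                if s_in * s_out < 0:
                    n += 1 if s_in > 0 else -1
        net.append(n)
    return net


def junction_coverage(plan, junctions: Sequence[float], gap: float,
                      pair: int = 20) -> list:
    """Open-time level at each junction, in full-gap-passage units.

    A point J is open while the leading edge lies in [J, J+gap]; summing the
    fractional crossing of that interval over every leading-edge leg gives
    the local fluence plateau level in units of one gap passage (one
    "traversal"), which converts normalised junction areas back to absolute
    open time.
    """
    xb = np.array([cp.bank_b[pair] for cp in plan.control_points])
    out = []
    for jn in junctions:
        level = 0.0
        for lo, hi in zip(xb, xb[1:]):
            lo, hi = min(lo, hi), max(lo, hi)
            level += max(0.0, min(hi, jn + gap) - max(lo, jn)) / gap
        out.append(level)
    return out


def reversal_analysis(
    profile: np.ndarray,
    x: np.ndarray,
    junctions: Sequence[float],
    reversal_counts: Optional[Sequence[float]] = None,
    net_turns: Optional[Sequence[int]] = None,
    junction_levels: Optional[Sequence[float]] = None,
    gap: Optional[float] = None,
    window: float = 0.5,
    inner: float = 0.2,
    smooth_px: int = 3,
) -> ReversalReport:
    """Quantify junction over/underdosing on a normalised (100%) profile.

    Per junction the peak overdose and trough underdose within ``window`` cm
    are taken after a ``smooth_px`` moving average, together with the signed
    excess area relative to baseline.  The over-travel excursion is a
    triangle of half-width ``delta`` and area fraction ``delta**2 / gap`` per
    net reversal, so with the aperture ``gap`` and the junction's net signed
    turn count (see :func:`junction_turn_balance`) the over-travel distance
    is recovered as ``sqrt(|area| * gap / |net|)`` — the area, unlike the
    peak, is insensitive to pixelisation and smoothing.  With per-junction
    reversal counts the overdose-per-reversal rate is a least-squares slope
    through zero.
    """
    sm = moving_average(np.nan_to_num(profile, nan=100.0), smooth_px)
    dx = float(np.mean(np.diff(x)))
    rows = []
    for j, jn in enumerate(junctions):
        sel = (x >= jn - window) & (x <= jn + window)
        seg = sm[sel]
        over = float(np.nanmax(seg) - 100.0)
        under = float(100.0 - np.nanmin(seg))
        # excess area of the junction feature over a per-side linear baseline
        # (the sides may sit on the inter-strip fluence ramp, so each side
        # gets its own straight-line fit from the outer part of the window)
        xs = x[sel]
        area = 0.0
        for side in (-1, 1):
            outer = (side * (xs - jn) >= inner + 0.05) & (side * (xs - jn) <= window)
            band = (side * (xs - jn) >= 0) & (side * (xs - jn) < inner)
            if outer.sum() >= 2 and band.any():
                coef = np.polyfit(xs[outer], seg[outer], 1)
                base = np.polyval(coef, xs[band])
                area += float(np.nansum((seg[band] - base) / 100.0) * dx)
        row = {"junction_cm": float(jn), "overdose_pct": over,
               "underdose_pct": under, "excess_area_cm": area}
        if gap is not None:
            net = (net_turns[j] if net_turns is not None else 1) or 1
            level = junction_levels[j] if junction_levels is not None else 1.0
            row["overtravel_cm"] = float(
                np.sqrt(abs(area) * gap * level / abs(net)))
        if reversal_counts is not None:
            row["reversals"] = float(reversal_counts[j])
        rows.append(row)
    rate = float("nan")
    if reversal_counts is not None:
        n = np.asarray(reversal_counts, dtype=float)
        od = np.array([r["overdose_pct"] for r in rows])
        if np.any(n > 0):
            rate = float(np.sum(n * od) / np.sum(n * n))
    return ReversalReport(rows=rows, rate_pct_per_reversal=rate)


def transition_analysis(
    profile: np.ndarray,
    x: np.ndarray,
    junctions: Sequence[float],
    thresholds: Sequence[float] = (2.0, 3.0),
    window: float = 1.5,
    mixing: float = 0.8,
    settle_threshold: float = 2.0,
) -> TransitionReport:
    """Width of the dose excursion around each dose-rate-change junction.

    The two plateaus flanking a junction may sit at slightly different
    normalised levels (the MU of a low-dose-rate strip is quantised to the
    machine's entry resolution), so each side's plateau level is fitted from
    the outer part of the window and bridged linearly across the aperture
    ``mixing`` zone ``[J - mixing, J]``; excursions are measured against that
    expectation.  Per threshold the report gives the longest connected run of
    ``|excess| > threshold`` in mm, and ``settle_mm`` — how far past the
    junction the profile still deviates more than ``settle_threshold``.
    """
    prof = np.nan_to_num(np.asarray(profile, dtype=float), nan=100.0)
    dx_mm = float(np.mean(np.diff(x))) * 10.0
    rows = []
    for jn in junctions:
        sel = np.nonzero((x >= jn - window) & (x <= jn + window))[0]
        xs = x[sel]
        seg = prof[sel]
        left = xs <= jn - mixing - 0.1
        right = xs >= jn + 0.6 * window
        l_lev = float(np.nanmedian(seg[left])) if left.any() else 100.0
        r_lev = float(np.nanmedian(seg[right])) if right.any() else 100.0
        base = np.where(xs <= jn - mixing, l_lev,
                        np.where(xs >= jn, r_lev,
                                 l_lev + (r_lev - l_lev)
                                 * (xs - jn + mixing) / mixing))
        exc = seg - base
        row = {"junction_cm": float(jn),
               "max_excursion_pct": float(exc[np.argmax(np.abs(exc))])}
        for thr in thresholds:
            out_mask = np.abs(exc) > thr
            width = run = 0
            for v in out_mask:
                run = run + 1 if v else 0
                width = max(width, run)
            row[f"width_{thr:g}pct_mm"] = width * dx_mm
        past = (xs > jn) & (np.abs(exc) > settle_threshold)
        row["settle_mm"] = float((xs[past].max() - jn) * 10.0) if past.any() else 0.0
        rows.append(row)
    return TransitionReport(rows=rows)


# ---------------------------------------------------------------------------
# chamber and imager reports
# ---------------------------------------------------------------------------

def chamber_report(
    static_readings: dict,
    arc_readings: dict,
    dmlc_readings: Optional[dict] = None,
    mu_levels: Optional[Sequence[float]] = None,
) -> ChamberReport:
    """Monitor-chamber stability: arc/static ratios, linearity, DMLC ratios.

    ``static_readings`` maps MU level -> reading; ``arc_readings`` maps MU
    level -> {sense: reading} for clockwise/counterclockwise arcs.
    ``dmlc_readings`` maps gantry-angle labels (numbers) and ``"arc"`` to
    gravity-gap readings; ratios are taken against the static-angle average.
    """
    if not static_readings:
        raise ValueError("static reference readings are required")
    ratios = {}
    for mu, r_static in static_readings.items():
        if mu in arc_readings:
            arcs = arc_readings[mu]
            vals = list(arcs.values()) if isinstance(arcs, dict) else list(arcs)
            ratios[mu] = float(np.mean(vals) / r_static)
    lin = float("nan")
    levels = sorted(mu_levels or static_readings)
    if len(levels) >= 2:
        lo, hi = levels[0], levels[-1]
        lin = abs((static_readings[hi] / hi) / (static_readings[lo] / lo) - 1.0)
    dmlc = {}
    if dmlc_readings:
        statics = [v for k, v in dmlc_readings.items() if not isinstance(k, str)]
        base = float(np.mean(statics))
        dmlc = {k: float(v / base) for k, v in dmlc_readings.items()}
    return ChamberReport(arc_static_ratio=ratios, linearity_deviation=lin,
                         dmlc_ratios=dmlc)


def center_pixel_report(centers_by_angle: dict) -> dict:
    """Per-angle deviation of the projected beam axis from the all-angle mean.

    ``centers_by_angle`` maps gantry angle -> (x, y) centre in cm on the
    imager.  Returns per-axis means and per-angle deviations.
    """
    if len(centers_by_angle) < 2:
        raise ValueError("need centres from at least two gantry angles")
    angles = list(centers_by_angle)
    arr = np.array([centers_by_angle[a] for a in angles], dtype=float)
    mean = arr.mean(axis=0)
    dev = arr - mean
    return {
        "mean_x_cm": float(mean[0]),
        "mean_y_cm": float(mean[1]),
        "deviation_cm": {a: (float(d[0]), float(d[1]))
                         for a, d in zip(angles, dev)},
    }
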