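"""Construction of the dynamic commissioning test deliveries.

Every generator returns a :class:`~vmatqa.machine.VmatPlan` built from a
:class:`~vmatqa.machine.MachineLimits` configuration.  Plans are assembled
from per-leaf-pair piecewise-linear trajectories parametrised by cumulative
MU: within a control-point segment every axis is a linear function of MU,
which is exactly the interpolation rule of the delivery controller, so the
emitted control points reproduce the intended motion with no discretisation
error.  Control-point MU values are quantised to the machine's MU entry
resolution at emission.

The MU settings of the speed-limit fields follow the sweep relation

    MU = (dMU/dt)_max * travel / v_max                                  (leaf/jaw)
    MU = (dMU/dt)_max * arc    / (dtheta/dt)_max                        (gantry)

and the strip deliveries keep the MU per strip and the MU spent moving
between strips constant so that a purely relative analysis is possible.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .machine import (
    N_LEAF_PAIRS,
    ControlPoint,
    MachineLimits,
    StripSpec,
    VmatPlan,
)

__all__ = [
    "DEFAULT_DRGS_FACTORS",
    "DEFAULT_MLC_SPEED_FACTORS",
    "gen_picket_fence",
    "gen_speed_limit_test",
    "gen_dr_gs_strip_test",
    "gen_mlc_speed_strip_test",
    "gen_reversal_test",
    "gen_dr_change_test",
    "gen_utility_fields",
]

# the eight DR:GS strip combinations, ending with the two over-maximum probes
DEFAULT_DRGS_FACTORS = (
    (1 / 32, 1 / 32), (1 / 16, 1 / 16), (1 / 8, 1 / 8), (1 / 4, 1 / 4),
    (1 / 2, 1 / 2), (1.0, 1.0), (1.2, 1.0), (1.0, 1.2),
)

# the seven MLC-speed:DR combinations
DEFAULT_MLC_SPEED_FACTORS = (
    (1 / 32, 1 / 32), (1 / 16, 1 / 16), (1 / 8, 1 / 8), (1 / 4, 1 / 4),
    (1 / 2, 1 / 2), (1.0, 1.0), (1.2, 1.2),
)

_PARK_X = -15.0  # cm; closed pairs sit here with zero opening


def _open_pair_range(field_size_y: float) -> range:
    """Leaf pairs whose 1 cm band centre lies inside the in-plane field."""
    half = field_size_y / 2.0
    lo = int(math.ceil(19.5 - half + 1e-9))
    hi = int(math.floor(19.5 + half - 1e-9))
    return range(max(lo, 0), min(hi, N_LEAF_PAIRS - 1) + 1)


def _quantize(mu: float, res: float) -> float:
    # round-half-up onto the MU entry grid, stabilised against float noise
    return round(math.floor(mu / res + 0.5) * res, 9)


def _assemble(
    name: str,
    pair_trajs: dict,
    total_mu: float,
    limits: MachineLimits,
    theta: Sequence[Sequence[float]] = ((0.0, 0.0),),
    jaws: Sequence[float] = (-20.0, 20.0),
    jaw_traj: Optional[dict] = None,
    dr_profile: Optional[Sequence[Sequence[float]]] = None,
    strip_specs: Optional[list] = None,
    energy_label: str = "6MV",
    notes: str = "",
) -> VmatPlan:
    """Merge per-pair (mu, a, b) trajectories into a control-point sequence.

    ``theta`` is a piecewise-linear (mu, angle) table, ``dr_profile`` a list of
    ``(mu_start, mu_end, dr_mu_min)`` rows giving the planned dose rate, and
    ``jaw_traj`` optional ``{"left": (mus, xs), "right": (mus, xs)}`` tables.
    """
    res = limits.mu_resolution
    grid = {0.0, total_mu}
    for mus, _, _ in pair_trajs.values():
        grid.update(mus)
    th = np.asarray(theta, dtype=float)
    grid.update(th[:, 0].tolist())
    if jaw_traj:
        for mus, _ in jaw_traj.values():
            grid.update(mus)
    if dr_profile:
        for lo, hi, _ in dr_profile:
            grid.update((lo, hi))
    total_q = _quantize(total_mu, res)
    mu_grid = sorted({min(_quantize(m, res), total_q)
                      for m in grid if -1e-9 <= m <= total_mu + 1e-9} | {0.0, total_q})
    mu_grid = np.asarray(mu_grid)
    mu_grid[0] = 0.0

    bank_a = np.full((len(mu_grid), N_LEAF_PAIRS), _PARK_X)
    bank_b = np.full((len(mu_grid), N_LEAF_PAIRS), _PARK_X)
    for pair, (mus, xa, xb) in pair_trajs.items():
        # snap breakpoints onto the MU entry grid keeping their positions, so
        # trajectory corners (reversal apexes, dwell starts) stay exact
        mq = [min(_quantize(m, res), total_q) for m in mus]
        bank_a[:, pair] = np.interp(mu_grid, mq, xa)
        bank_b[:, pair] = np.interp(mu_grid, mq, xb)
    thetas = np.interp(mu_grid, th[:, 0], th[:, 1])
    if jaw_traj:
        jl = np.interp(mu_grid, *jaw_traj["left"])
        jr = np.interp(mu_grid, *jaw_traj["right"])
    else:
        jl = np.full(len(mu_grid), float(jaws[0]))
        jr = np.full(len(mu_grid), float(jaws[1]))

    cps = [
        ControlPoint(cum_mu=float(m), gantry_angle=float(t),
                     bank_a=bank_a[i], bank_b=bank_b[i],
                     jaw_left=float(jl[i]), jaw_right=float(jr[i]))
        for i, (m, t) in enumerate(zip(mu_grid, thetas))
    ]
    seg_dr = None
    if dr_profile:
        rows = np.asarray(dr_profile, dtype=float)
        mids = 0.5 * (mu_grid[:-1] + mu_grid[1:])
        seg_dr = []
        for m in mids:
            hit = rows[(rows[:, 0] - res <= m) & (m <= rows[:, 1] + res)]
            seg_dr.append(float(hit[0, 2]) if len(hit) else None)
    return VmatPlan(name=name, control_points=cps, strip_specs=strip_specs,
                    segment_dr=seg_dr, energy_label=energy_label, notes=notes)


# ---------------------------------------------------------------------------
# picket fence
# ---------------------------------------------------------------------------

def gen_picket_fence(
    limits: MachineLimits,
    field_size: float = 25.0,
    gap: float = 0.5,
    picket_positions: Sequence[float] = (-9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0),
    picket_width: float = 0.1,
    arc: Optional[float] = 356.0,
    static_angle: float = 0.0,
    errors: Sequence[dict] = (),
    sweep_speed: float = 0.4,
    dr_bin: int = 0,
) -> VmatPlan:
    """Dynamic picket fence: a moving gap with enhanced narrow strips.

    Both banks sweep continuously at ``sweep_speed``; at each picket the
    leading leaf advances over the strip at full leaf speed and then holds
    until back on schedule, and the trailing leaf holds at the strip entrance
    and then advances at full speed.  The two manoeuvres together add a
    constant extra open time ``w * (1/v - 1/v_max)`` over exactly the strip
    ``[p, p+w]`` and nothing outside it, producing a rectangular fluence
    picket of the programmed width.

    ``errors`` entries are ``{"leaf_pair": i, "widen_to": cm}`` or
    ``{"leaf_pair": i, "shift": cm}``; with any error present the default gap
    becomes 0.6 cm so adjacent pairs never violate the minimum-gap rule.
    """
    pk = sorted(picket_positions)
    if pk and min(np.diff(pk), default=np.inf) <= gap:
        raise ValueError("picket spacing must exceed the gap")
    if picket_width >= gap:
        raise ValueError("picket width must be smaller than the gap")
    if errors and gap == 0.5:
        gap = 0.6
    half = field_size / 2.0
    if pk and (pk[0] < -half or pk[-1] > half):
        raise ValueError("pickets must lie inside the field")
    v = sweep_speed
    vj = limits.mlc_speed_max
    if v >= vj:
        raise ValueError("sweep speed must be below the leaf speed limit")
    r = limits.bin_table().rate_mu_s(dr_bin)
    total_mu = r * field_size / v

    def pair_traj(pickets: Sequence[float], w: float):
        # leading bank B sweeps -half -> half; trailing bank A trails by `gap`
        mus_b, xb = [0.0], [-half]
        mus_a, xa = [0.0], [-half - gap]
        for p in pickets:
            m0 = r * (p + half) / v
            mu_j = r * w / vj
            mu_w = r * w / v
            mus_b += [m0, m0 + mu_j, m0 + mu_w]
            xb += [p, p + w, p + w]
            m1 = r * (p + half + gap) / v
            mus_a += [m1, m1 + (mu_w - mu_j), m1 + mu_w]
            xa += [p, p, p + w]
        mus_b.append(total_mu)
        xb.append(half)
        mus_a.append(total_mu)
        xa.append(half - gap)
        # merge the two banks' breakpoints onto one MU grid
        mus = sorted(set(mus_a) | set(mus_b))
        return (mus,
                np.interp(mus, mus_a, xa).tolist(),
                np.interp(mus, mus_b, xb).tolist())

    err_by_pair = {}
    for e in errors:
        spec = dict(e)
        pair = int(spec.pop("leaf_pair"))
        err_by_pair[pair] = spec

    trajs = {}
    nominal_traj = pair_traj(pk, picket_width)
    for pair in _open_pair_range(field_size):
        spec = err_by_pair.get(pair)
        if not spec:
            trajs[pair] = nominal_traj
            continue
        w = float(spec.get("widen_to", picket_width))
        shift = float(spec.get("shift", 0.0))
        trajs[pair] = pair_traj([p + shift for p in pk], w)

    if arc is not None:
        theta = ((0.0, 0.0), (total_mu, float(arc)))
    else:
        theta = ((0.0, float(static_angle)), (total_mu, float(static_angle)))
    specs = [
        StripSpec(index=i, x_start=p, x_end=p + picket_width,
                  planned_mu=r * picket_width * (1 / v - 1 / vj))
        for i, p in enumerate(pk)
    ]
    nominal = limits.bin_table().nominal_bins[dr_bin]
    notes = (f"picket fence gap={gap} cm, width={picket_width} cm, "
             f"sweep {v} cm/s at DR bin {dr_bin} ({nominal} MU/min)"
             + (f", errors={errors}" if errors else ""))
    plan = _assemble("picket_fence" + ("_errors" if errors else ""),
                     trajs, total_mu, limits, theta=theta,
                     jaws=(-half - gap, half),
                     dr_profile=[(0.0, total_mu, limits.bin_table().exact_bins[dr_bin])],
                     strip_specs=specs, notes=notes)
    return plan


# ---------------------------------------------------------------------------
# maximum-speed consistency fields
# ---------------------------------------------------------------------------

def gen_speed_limit_test(
    axis: str,
    travel: float,
    limits: MachineLimits,
    mu_override: Optional[float] = None,
    gap: float = 0.8,
) -> VmatPlan:
    """Single-segment field whose MU puts the named axis exactly at its limit.

    At the emitted MU the axis must run at its configured maximum for the
    top dose-rate bin to remain feasible; lowering the MU by one entry step
    drops the displayed dose rate to half-maximum, which is the observable
    used to invert the speed limit.
    """
    if travel <= 0:
        raise ValueError("travel must be > 0")
    r = limits.dr_max_mu_s
    if axis == "mlc":
        mu = mu_override if mu_override is not None else r * travel / limits.mlc_speed_max
        half = travel / 2.0
        trajs = {
            p: ([0.0, mu], [-half - gap, half - gap], [-half, half])
            for p in _open_pair_range(10.0)
        }
        plan = _assemble(f"speed_limit_mlc", trajs, mu, limits,
                         jaws=(-half - gap, half),
                         notes=f"DMLC sweep {travel} cm, gap {gap} cm")
    elif axis == "jaw":
        mu = mu_override if mu_override is not None else r * travel / limits.jaw_speed_max
        trajs = {p: ([0.0, mu], [-8.0, -8.0], [8.0, 8.0]) for p in _open_pair_range(10.0)}
        jt = {"left": ([0.0, mu], [-travel / 2 - 5, travel / 2 - 5]),
              "right": ([0.0, mu], [-travel / 2 + 5, travel / 2 + 5])}
        plan = _assemble("speed_limit_jaw", trajs, mu, limits, jaw_traj=jt,
                         notes=f"backup jaw sweep {travel} cm")
    elif axis == "gantry":
        mu = mu_override if mu_override is not None else r * travel / limits.gantry_speed_max
        trajs = {p: ([0.0, mu], [-5.0, -5.0], [5.0, 5.0]) for p in _open_pair_range(10.0)}
        plan = _assemble("speed_limit_gantry", trajs, mu, limits,
                         theta=((0.0, 0.0), (mu, travel)), jaws=(-5.0, 5.0),
                         notes=f"arc {travel} deg at nominal maximum gantry speed")
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return plan


# ---------------------------------------------------------------------------
# DR : gantry-speed strips
# ---------------------------------------------------------------------------

def gen_dr_gs_strip_test(
    limits: MachineLimits,
    mu_strip: float = 20.0,
    factor_pairs: Sequence[Sequence[float]] = DEFAULT_DRGS_FACTORS,
    strip_width: float = 3.0,
    max_arc: float = 358.0,
) -> VmatPlan:
    """Strips of paired dose rate and gantry speed, equal MU per strip.

    A 3 cm slit dwells over each strip while the gantry arcs through the span
    given by ``theta_i = MU_strip * GS_i / DR_i``; between strips (and for a
    lead-in/out strip width at either end, which equalises the move
    contribution at every strip midpoint) the slit translates at
    ``0.75 * v_max`` with the dose rate at max/8, so the inter-strip time and
    MU are constant: ``t = w / (0.75 v_max)``, ``MU = t * DR_move``.
    """
    r_max = limits.dr_max_mu_s
    v_move = 0.75 * limits.mlc_speed_max
    r_move = r_max / 8.0
    t_move = strip_width / v_move
    mu_move = t_move * r_move
    if mu_strip <= mu_move:
        raise ValueError("mu_strip must exceed the inter-strip MU")
    n = len(factor_pairs)
    x0 = -n * strip_width / 2.0
    gs = [f_gs * limits.gantry_speed_max for _, f_gs in factor_pairs]
    dr = [f_dr * r_max for f_dr, _ in factor_pairs]

    # MU and gantry schedule
    mu_pts, th_pts, dr_rows, specs = [0.0], [0.0], [], []
    mus, xa, xb = [0.0], [x0 - strip_width], [x0]
    mu = 0.0
    th = 0.0

    def advance(d_mu, d_th, rate):
        nonlocal mu, th
        dr_rows.append((mu, mu + d_mu, rate * 60.0))
        mu += d_mu
        th += d_th
        mu_pts.append(mu)
        th_pts.append(th)

    # lead-in move at the first strip's gantry speed
    advance(mu_move, t_move * min(gs[0], limits.gantry_speed_max), r_move)
    mus.append(mu)
    xa.append(x0)
    xb.append(x0 + strip_width)
    arc_spans = []
    for i, (f_dr, f_gs) in enumerate(factor_pairs):
        span = mu_strip * gs[i] / dr[i]
        arc_spans.append(span)
        advance(mu_strip, span, dr[i])
        mus.append(mu)
        xa.append(xa[-1])
        xb.append(xb[-1])
        move_gs = min(gs[i], limits.gantry_speed_max)
        advance(mu_move, t_move * move_gs, r_move)
        mus.append(mu)
        xa.append(xa[-1] + strip_width)
        xb.append(xb[-1] + strip_width)
        specs.append(StripSpec(index=i, x_start=x0 + i * strip_width,
                               x_end=x0 + (i + 1) * strip_width,
                               dr_factor=f_dr, gs_factor=f_gs,
                               planned_mu=mu_strip, arc_span=span))
    total_arc = th
    if total_arc >= max_arc:
        raise ValueError(
            f"total arc {total_arc:.2f} deg >= {max_arc} deg; reduce mu_strip "
            f"(strip spans sum to {sum(arc_spans):.2f} deg)")
    total_mu = mu
    trajs = {p: (mus, xa, xb) for p in _open_pair_range(24.0)}
    plan = _assemble("dr_gs_strips", trajs, total_mu, limits,
                     theta=list(zip(mu_pts, th_pts)),
                     jaws=(x0 - strip_width - 0.5, -x0 + strip_width + 0.5),
                     dr_profile=dr_rows, strip_specs=specs,
                     notes=f"eight DR:GS strips, MU/strip={mu_strip}, "
                           f"inter-strip MU={mu_move:.3g}, arc={total_arc:.2f} deg")
    return plan


# ---------------------------------------------------------------------------
# MLC-speed : DR strips
# ---------------------------------------------------------------------------

def gen_mlc_speed_strip_test(
    limits: MachineLimits,
    factor_pairs: Sequence[Sequence[float]] = DEFAULT_MLC_SPEED_FACTORS,
    gap: float = 0.8,
    strip_width: float = 3.0,
    lateral_margin: float = 1.5,
) -> VmatPlan:
    """Sweeping-gap strips of paired MLC speed and dose rate, equal dose.

    Because speed and dose rate share the same factor, the leaf displacement
    per MU is the machine constant ``v_max / DR_max`` in every strip and the
    MU per strip is ``w * DR_max / v_max`` (15 MU for 3 cm at the defaults).
    The gantry speed is constant, fixed by the MU-per-degree floor evaluated
    at the lowest bin: ``GS = (DR_max/32) / 0.1 MU/deg``.  Margins of
    ``lateral_margin`` at either end sweep at the edge strips' settings so
    the fluence plateau spans the full open-field width.
    """
    if gap < limits.min_gap:
        raise ValueError("gap below the minimum leaf gap gives unreliable "
                         "delivery at maximum leaf speed")
    r_max = limits.dr_max_mu_s
    v_max = limits.mlc_speed_max
    dx_dmu = v_max / r_max
    gs = (r_max / 32.0) / limits.mu_per_degree_min  # deg/s, MU-per-degree floor at max/32
    n = len(factor_pairs)
    half = n * strip_width / 2.0
    lo, hi = -half - lateral_margin, half + lateral_margin

    # rigid-gap translation: aperture left edge from lo-gap to hi
    start_a, end_a = lo - gap, hi
    total_mu = (end_a - start_a) / dx_dmu
    trajs = {
        p: ([0.0, total_mu], [start_a, end_a], [start_a + gap, end_a + gap])
        for p in _open_pair_range(24.0)
    }

    # planned DR per MU interval: governed by the strip under the leading edge
    bounds = [lo] + [-half + k * strip_width for k in range(n + 1)] + [hi + gap]
    rates = [factor_pairs[0][1]] + [fp[1] for fp in factor_pairs] + [factor_pairs[-1][1]]
    dr_rows, th_pts, mu_pts = [], [0.0], [0.0]
    th = 0.0
    specs = []
    for k in range(len(bounds) - 1):
        b_lo, b_hi = bounds[k], bounds[k + 1]
        mu_lo = (b_lo - (start_a + gap)) / dx_dmu
        mu_hi = (b_hi - (start_a + gap)) / dx_dmu
        mu_lo, mu_hi = max(mu_lo, 0.0), min(mu_hi, total_mu)
        if mu_hi <= mu_lo:
            continue
        rate = rates[k] * r_max
        dr_rows.append((mu_lo, mu_hi, rate * 60.0))
        # time in this interval at the deliverable rate sets the arc increment
        deliverable = min(rate, r_max)
        th += (mu_hi - mu_lo) / deliverable * gs
        mu_pts.append(mu_hi)
        th_pts.append(th)
    for i, (f_v, f_dr) in enumerate(factor_pairs):
        specs.append(StripSpec(index=i, x_start=-half + i * strip_width,
                               x_end=-half + (i + 1) * strip_width,
                               mlc_speed_factor=f_v, dr_factor=f_dr,
                               planned_mu=strip_width * r_max / v_max))
    plan = _assemble("mlc_speed_strips", trajs, total_mu, limits,
                     theta=list(zip(mu_pts, th_pts)),
                     jaws=(lo - 0.5, hi + 0.5), dr_profile=dr_rows,
                     strip_specs=specs,
                     notes=f"{n} MLC-speed:DR strips, gap {gap} cm, "
                           f"GS {gs:.4g} deg/s, MU/strip "
                           f"{strip_width * r_max / v_max:.4g}")
    return plan


# ---------------------------------------------------------------------------
# MLC reversal strips
# ---------------------------------------------------------------------------

def gen_reversal_test(
    limits: MachineLimits,
    speed_factors: Sequence[float] = (1.0, 0.95, 0.90, 0.18),
    strip_width: float = 4.0,
    junctions: Sequence[float] = (-5.6, -1.6, 3.6, 7.6, 10.6),
    traversal_counts: Sequence[float] = (1.0, 3.0, 5.0, 7.0, 5.5),
    gap: float = 0.8,
) -> list:
    """Multi-traversal reversal strips; one plan per leaf-speed factor.

    The aperture zig-zags along a single continuous path whose turning points
    sit on the strip junctions, giving each strip an odd number of full
    traversals (a continuous left-to-right path cannot produce an even
    count) plus a final half traversal in the last strip.  The dose in each
    strip is proportional to its traversal count; the per-junction reversal
    counts implied by the path are recorded in the plan notes and strip
    metadata.  All strips run at half the maximum dose rate.
    """
    jn = list(junctions)
    bounds = [jn[0] - strip_width] + jn
    r = limits.dr_max_mu_s / 2.0
    plans = []
    for f in speed_factors:
        v = f * limits.mlc_speed_max
        # waypoints of the leading edge b
        wps = [bounds[0]]
        for k, count in enumerate(traversal_counts):
            lo, hi = bounds[k], bounds[k + 1]
            full = int(count)
            frac = count - full
            for p in range(full):
                wps.append(hi if p % 2 == 0 else lo)
            if frac:
                # end the partial pass where the strip centre has accumulated
                # exactly `frac` of one full-gap passage of the leading edge
                centre = 0.5 * (lo + hi)
                wps.append(centre + frac * gap if full % 2 == 0
                           else centre + (1 - frac) * gap)
        mus, xb = [0.0], [wps[0]]
        mu = 0.0
        for w0, w1 in zip(wps, wps[1:]):
            mu += abs(w1 - w0) * r / v
            mus.append(mu)
            xb.append(w1)
        total_mu = mu
        xa = [x - gap for x in xb]
        trajs = {p: (mus, xa, xb) for p in _open_pair_range(20.0)}
        rev_at = {}
        for w0, w1, w2 in zip(wps, wps[1:], wps[2:]):
            if (w1 - w0) * (w2 - w1) < 0:
                rev_at[w1] = rev_at.get(w1, 0) + 1
        specs = [
            StripSpec(index=k, x_start=bounds[k], x_end=bounds[k + 1],
                      mlc_speed_factor=f, dr_factor=0.5,
                      traversal_count=traversal_counts[k],
                      planned_mu=traversal_counts[k] * gap * r / v)
            for k in range(len(traversal_counts))
        ]
        plan = _assemble(f"reversal_f{f:g}", trajs, total_mu, limits,
                         jaws=(bounds[0] - gap - 0.5, bounds[-1] + 0.5),
                         dr_profile=[(0.0, total_mu, r * 60.0)],
                         strip_specs=specs,
                         notes=f"reversal strips, leaf speed {v:g} cm/s "
                               f"({f:g} x max), reversals at "
                               f"{sorted(rev_at.items())}")
        plans.append(plan)
    return plans


# ---------------------------------------------------------------------------
# dose-rate change strips
# ---------------------------------------------------------------------------

def gen_dr_change_test(
    direction: str,
    limits: MachineLimits,
    mlc_speed_factor: float = 0.5,
    reference_speed: float = 0.25,
    gap: float = 0.8,
    strip_width: float = 3.0,
) -> tuple:
    """Instantaneous dose-rate steps under a constant-speed sweeping gap.

    Eight strips whose dose rates double from max/32 up to max, with the last
    two probing the extreme max/32 -> max jump; the ``decrease`` variant
    reverses the sequence.  Leaf speed is constant (half the maximum by
    default) so the fluence per strip is proportional to its dose rate.  The
    gantry speed is the MU-per-degree-floor value at the lowest bin.  Returns
    ``(test_plan, reference_plan)`` where the reference differs only in its
    leaf speed.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    fr = [1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 1 / 32, 1.0]
    if direction == "decrease":
        fr = fr[::-1]
    r_max = limits.dr_max_mu_s
    gs = (r_max / 32.0) / limits.mu_per_degree_min
    n = len(fr)
    half = n * strip_width / 2.0

    def build(v: float, tag: str) -> VmatPlan:
        start_a, end_a = -half - gap, half
        # leading-edge position controls which strip's rate applies
        bounds = [-half + k * strip_width for k in range(n + 1)]
        seg_bounds = [start_a + gap] + bounds[1:-1] + [end_a + gap]
        mus, xb = [0.0], [start_a + gap]
        dr_rows, th_pts, mu_pts = [], [0.0], [0.0]
        mu, th = 0.0, 0.0
        for k in range(len(seg_bounds) - 1):
            b_lo, b_hi = seg_bounds[k], seg_bounds[k + 1]
            rate = fr[min(k, n - 1)] * r_max
            d_mu = (b_hi - b_lo) / v * rate
            dr_rows.append((mu, mu + d_mu, rate * 60.0))
            th += (b_hi - b_lo) / v * gs
            mu += d_mu
            mus.append(mu)
            xb.append(b_hi)
            mu_pts.append(mu)
            th_pts.append(th)
        total_mu = mu
        xa = [x - gap for x in xb]
        trajs = {p: (mus, xa, xb) for p in _open_pair_range(20.0)}
        specs = [
            StripSpec(index=k, x_start=bounds[k], x_end=bounds[k + 1],
                      dr_factor=fr[k], mlc_speed_factor=v / limits.mlc_speed_max,
                      planned_mu=strip_width / v * fr[k] * r_max)
            for k in range(n)
        ]
        return _assemble(f"dr_{direction}_{tag}", trajs, total_mu, limits,
                         theta=list(zip(mu_pts, th_pts)),
                         jaws=(start_a - 0.5, end_a + gap + 0.5),
                         dr_profile=dr_rows, strip_specs=specs,
                         notes=f"DR {direction} strips, leaf speed {v:g} cm/s, "
                               f"GS {gs:.4g} deg/s")

    test = build(mlc_speed_factor * limits.mlc_speed_max, "test")
    ref = build(reference_speed, "ref")
    return test, ref


# ---------------------------------------------------------------------------
# utility fields
# ---------------------------------------------------------------------------

def gen_utility_fields(kind: str, limits: MachineLimits, **params) -> VmatPlan:
    """Static/arc open fields, MU-linearity fields, and the gravity-gap sweep.

    * ``open_field`` — static square field (default 25 x 25 cm) at a chosen
      dose-rate bin; used as the normalisation reference for strip tests.
    * ``static_mu`` / ``arc_mu`` — 10 x 10 cm monitor-chamber stability
      fields at 36 or 1000 MU, static or over a 360 deg arc.
    * ``dmlc_gravity`` — 1 cm gap sweeping a 23 cm span at 0.74 cm/s; for the
      arc variant the gantry speed is chosen so a 180 deg arc completes
      exactly with the sweep (180 / (23 / 0.74) = 5.79 deg/s).
    """
    r_max = limits.dr_max_mu_s
    if kind == "open_field":
        size = params.get("field_size", 25.0)
        mu = params.get("mu", 100.0)
        k = params.get("dr_bin", 0)
        half = size / 2.0
        trajs = {p: ([0.0, mu], [-half, -half], [half, half])
                 for p in _open_pair_range(size)}
        return _assemble(f"open_field_bin{k}", trajs, mu, limits,
                         jaws=(-half, half),
                         dr_profile=[(0.0, mu, limits.bin_table().exact_bins[k])],
                         notes=f"static {size}x{size} open field at bin {k}")
    if kind in ("static_mu", "arc_mu"):
        mu = params.get("mu", 36.0)
        k = params.get("dr_bin", limits.n_dr_bins - 1 if mu <= 100 else 0)
        trajs = {p: ([0.0, mu], [-5.0, -5.0], [5.0, 5.0])
                 for p in _open_pair_range(10.0)}
        theta = ((0.0, 0.0), (mu, 360.0)) if kind == "arc_mu" else ((0.0, 0.0),)
        return _assemble(f"{kind}_{mu:g}", trajs, mu, limits, theta=theta,
                         jaws=(-5.0, 5.0),
                         dr_profile=[(0.0, mu, limits.bin_table().exact_bins[k])],
                         notes=f"{kind} {mu:g} MU chamber-stability field")
    if kind == "dmlc_gravity":
        span = params.get("span", 23.0)
        g = params.get("gap", 1.0)
        v = params.get("speed", 0.74)
        arc = params.get("arc", 180.0)
        static_angle = params.get("static_angle")
        mu = r_max * span / v
        half = span / 2.0
        trajs = {p: ([0.0, mu], [-half - g, half - g], [-half, half])
                 for p in _open_pair_range(10.0)}
        if static_angle is None:
            theta = ((0.0, 0.0), (mu, arc))
            gs = arc / (span / v)
        else:
            theta = ((0.0, float(static_angle)),)
            gs = 0.0
        return _assemble("dmlc_gravity", trajs, mu, limits, theta=theta,
                         jaws=(-half - g, half),
                         dr_profile=[(0.0, mu, limits.dr_max)],
                         notes=f"gravity gap {g} cm over {span} cm at {v} cm/s"
                               + (f", arc GS {gs:.3g} deg/s" if gs else ""))
    raise ValueError(f"unknown utility field kind {kind!r}")
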