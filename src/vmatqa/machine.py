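"""Machine model: limits, dose-rate bins, segment kinematics and plan validation.

The delivery system modelled here is an Elekta-style linac: the dose rate is
not continuously variable but *binned* in multiples of one half of the machine
maximum, and during a dynamic delivery the controller runs each segment at the
highest bin for which no axis (MLC leaves, backup jaws, gantry) would have to
exceed its speed limit.  All positions are expressed in cm projected to the
isocenter plane, angles in degrees, dose in monitor units (MU).  Dose rates
are entered in MU/min (as printed on the console) and converted to MU/s
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

N_LEAF_PAIRS = 40
LEAF_WIDTH_CM = 1.0  # in-plane width of one leaf pair at isocenter
MAX_LEAF_POS_CM = 20.0

__all__ = [
    "N_LEAF_PAIRS",
    "LEAF_WIDTH_CM",
    "MAX_LEAF_POS_CM",
    "MachineLimits",
    "DoseRateBinTable",
    "ControlPoint",
    "StripSpec",
    "VmatPlan",
    "SegmentKinematics",
    "Violation",
    "build_bin_table",
    "segment_kinematics",
    "select_bin",
    "validate_plan",
    "invert_max_speed",
]


@dataclass(frozen=True)
class MachineLimits:
    """Nominal maxima and constraints of the delivery system.

    Defaults are the nominal values of the machine commissioned in the study
    this toolkit reproduces: 600 MU/min maximum dose rate in 6 binary bins,
    2.0 cm/s MLC leaves, 1.5 cm/s backup jaws, 6.0 deg/s gantry, 0.5 cm
    minimum leaf gap and a 0.1 MU/deg floor on dynamic segments.
    """

    dr_max: float = 600.0           # MU/min
    mlc_speed_max: float = 2.0      # cm/s at isocenter
    jaw_speed_max: float = 1.5      # cm/s
    gantry_speed_max: float = 6.0   # deg/s
    n_dr_bins: int = 6
    min_gap: float = 0.5            # cm
    mu_per_degree_min: float = 0.1  # MU/deg
    mu_resolution: float = 0.1      # MU; fractional MU entry is allowed
    dr_switch_time: float = 0.25    # s, literature value for bin changes
    gantry_inertia_distance: float = 0.0  # deg; exposed, not calculated

    def __post_init__(self) -> None:
        for name in (
            "dr_max", "mlc_speed_max", "jaw_speed_max", "gantry_speed_max",
            "min_gap", "mu_per_degree_min", "mu_resolution",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_dr_bins < 1:
            raise ValueError("n_dr_bins must be >= 1")
        if self.mu_resolution > 1:
            raise ValueError("mu_resolution must be <= 1 MU")
        if self.dr_switch_time < 0 or self.gantry_inertia_distance < 0:
            raise ValueError("times and distances must be >= 0")

    @property
    def dr_max_mu_s(self) -> float:
        return self.dr_max / 60.0

    def bin_table(self) -> "DoseRateBinTable":
        return build_bin_table(self.dr_max, self.n_dr_bins)

    def replace(self, **kw) -> "MachineLimits":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseRateBinTable:
    """Binned dose rates: bin k runs at dr_max / 2**k (MU/min).

    ``nominal_bins`` are the integer MU/min values a planner would enter into
    a TPS (round-half-up of the exact bin, e.g. 18.75 -> 19).
    """

    dr_max: float
    exact_bins: tuple
    nominal_bins: tuple

    def __len__(self) -> int:
        return len(self.exact_bins)

    def rate_mu_s(self, k: int) -> float:
        return self.exact_bins[k] / 60.0


def build_bin_table(dr_max: float, n_bins: int) -> DoseRateBinTable:
    """Construct the binary dose-rate bin table for a machine maximum."""
    if dr_max <= 0 or n_bins < 1:
        raise ValueError("dr_max must be > 0 and n_bins >= 1")
    exact = tuple(dr_max / 2.0 ** k for k in range(int(n_bins)))
    # round-half-up so 18.75 -> 19, matching the console's nominal table
    nominal = tuple(int(np.floor(b + 0.5)) for b in exact)
    return DoseRateBinTable(dr_max=dr_max, exact_bins=exact, nominal_bins=nominal)


@dataclass
class ControlPoint:
    """One row of a dynamic plan: cumulative MU plus simultaneous axis positions.

    Gantry angles are stored on a continuous scale (no modular wrap inside a
    plan) so that speeds difference cleanly across multi-quadrant arcs.
    ``bank_a`` holds the left (lower-x) leaf tips, ``bank_b`` the right ones;
    the aperture of pair i is the interval [bank_a[i], bank_b[i]].
    """

    cum_mu: float
    gantry_angle: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    jaw_left: float = -20.0
    jaw_right: float = 20.0
    collimator_angle: float = 0.0

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        if self.bank_a.shape != (N_LEAF_PAIRS,) or self.bank_b.shape != (N_LEAF_PAIRS,):
            raise ValueError(f"leaf banks must each hold {N_LEAF_PAIRS} positions")


@dataclass
class StripSpec:
    """Metadata describing one strip of a strip-type test delivery."""

    index: int
    x_start: float
    x_end: float
    dr_factor: float = 1.0
    gs_factor: float = 1.0
    mlc_speed_factor: float = 1.0
    planned_mu: float = 0.0
    traversal_count: float = 1.0
    arc_span: float = 0.0

    def __post_init__(self) -> None:
        if self.x_end <= self.x_start:
            raise ValueError("x_end must exceed x_start")
        if self.planned_mu < 0:
            raise ValueError("planned_mu must be >= 0")

    @property
    def x_mid(self) -> float:
        return 0.5 * (self.x_start + self.x_end)

    @property
    def width(self) -> float:
        return self.x_end - self.x_start


@dataclass
class VmatPlan:
    """An ordered control-point sequence with optional strip metadata.

    ``segment_dr`` optionally records the planned dose rate (MU/min) for each
    inter-control-point segment; the controller treats it as an upper bound on
    the bin it may select, never as permission to exceed axis limits.
    """

    name: str
    control_points: list
    energy_label: str = "6MV"
    strip_specs: Optional[list] = None
    segment_dr: Optional[list] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("a plan needs at least 2 control points")
        mus = [cp.cum_mu for cp in self.control_points]
        if mus[0] != 0:
            raise ValueError("first control point must have cum_mu == 0")
        if any(b < a for a, b in zip(mus, mus[1:])):
            raise ValueError("cum_mu must be non-decreasing")
        if self.segment_dr is not None and len(self.segment_dr) != len(self.control_points) - 1:
            raise ValueError("segment_dr must have one entry per segment")

    @property
    def total_mu(self) -> float:
        return self.control_points[-1].cum_mu

    def segments(self) -> Iterable[tuple]:
        return zip(self.control_points[:-1], self.control_points[1:])


@dataclass(frozen=True)
class SegmentKinematics:
    """Per-segment differences driving bin selection and timing."""

    d_mu: float
    d_theta: float
    max_leaf_travel: float
    jaw_travel: float

    def duration_at(self, dr_mu_s: float) -> float:
        """Segment duration at a given dose rate (MU/s), ignoring axis caps."""
        return self.d_mu / dr_mu_s


def segment_kinematics(cp_i: ControlPoint, cp_j: ControlPoint) -> SegmentKinematics:
    """Difference two consecutive control points of one plan."""
    d_mu = cp_j.cum_mu - cp_i.cum_mu
    if d_mu < 0:
        raise ValueError("decreasing cumulative MU: corrupt plan")
    travel = float(
        max(
            np.max(np.abs(cp_j.bank_a - cp_i.bank_a)),
            np.max(np.abs(cp_j.bank_b - cp_i.bank_b)),
        )
    )
    jaw = max(abs(cp_j.jaw_left - cp_i.jaw_left), abs(cp_j.jaw_right - cp_i.jaw_right))
    return SegmentKinematics(
        d_mu=float(d_mu),
        d_theta=abs(cp_j.gantry_angle - cp_i.gantry_angle),
        max_leaf_travel=travel,
        jaw_travel=float(jaw),
    )


# slack for "speed exactly at the limit counts as feasible" under float arithmetic
_REL_EPS = 1e-9


def select_bin(
    seg: SegmentKinematics, limits: MachineLimits
) -> tuple:
    """Pick the dose-rate bin the controller would run a segment at.

    Returns ``(bin_index, limiting_axis)`` where ``limiting_axis`` names the
    axis that forbids the next-higher bin (``"none"`` for bin 0), plus a third
    element ``capped`` that is True when even the lowest bin cannot satisfy
    every axis limit (the controller then caps the axis at its maximum and
    stretches the segment in time).
    """
    if seg.d_mu <= 0:
        if seg.max_leaf_travel > 0 or seg.jaw_travel > 0 or seg.d_theta > 0:
            raise ValueError("zero-MU segment with motion: instantaneous move")
        return 0, "none", False
    table = limits.bin_table()

    def blocking_axis(rate_mu_s: float) -> Optional[str]:
        t = seg.d_mu / rate_mu_s
        # report the most-demanding axis relative to its limit
        ratios = {
            "mlc": seg.max_leaf_travel / t / limits.mlc_speed_max,
            "jaw": seg.jaw_travel / t / limits.jaw_speed_max,
            "gantry": seg.d_theta / t / limits.gantry_speed_max,
        }
        axis, worst = max(ratios.items(), key=lambda kv: kv[1])
        return axis if worst > 1 + _REL_EPS else None

    for k in range(len(table)):
        if blocking_axis(table.rate_mu_s(k)) is None:
            if k == 0:
                return 0, "none", False
            return k, blocking_axis(table.rate_mu_s(k - 1)), False
    k = len(table) - 1
    return k, blocking_axis(table.rate_mu_s(k)), True


@dataclass(frozen=True)
class Violation:
    """One plan-validation finding; violations are data, not exceptions."""

    segment: int
    kind: str      # mu_floor | gap | position | mu_order | leaf_speed-like
    value: float
    limit: float
    detail: str = ""


def validate_plan(plan: VmatPlan, limits: MachineLimits) -> list:
    """Check a plan against the physical constraints of the machine.

    Flags every dynamic segment whose MU per degree (evaluated at the maximum
    gantry speed, i.e. the worst case) falls below the controller floor, every
    leaf-pair opening between zero and the minimum gap (an exactly closed pair
    counts as parked), out-of-range positions, and non-monotone MU.  An empty
    list means the plan is deliverable.
    """
    out: list = []
    cps = plan.control_points
    for idx, cp in enumerate(cps):
        gaps = cp.bank_b - cp.bank_a
        bad = np.where((gaps > 1e-12) & (gaps < limits.min_gap - 1e-9))[0]
        for i in bad:
            out.append(Violation(idx, "gap", float(gaps[i]), limits.min_gap,
                                 f"pair {i} opening below minimum gap"))
        if gaps.min() < -1e-12:
            i = int(np.argmin(gaps))
            out.append(Violation(idx, "gap", float(gaps[i]), 0.0,
                                 f"pair {i} banks crossed"))
        for arr, nm in ((cp.bank_a, "bank_a"), (cp.bank_b, "bank_b")):
            if np.any(np.abs(arr) > MAX_LEAF_POS_CM + 1e-9):
                out.append(Violation(idx, "position",
                                     float(np.max(np.abs(arr))), MAX_LEAF_POS_CM,
                                     f"{nm} outside leaf travel range"))
    for s, (a, b) in enumerate(plan.segments()):
        d_mu = b.cum_mu - a.cum_mu
        if d_mu < 0:
            out.append(Violation(s, "mu_order", d_mu, 0.0, "cumulative MU decreases"))
            continue
        d_theta = abs(b.gantry_angle - a.gantry_angle)
        if d_theta > 1e-12 and d_mu > 0:
            mu_per_deg = d_mu / d_theta
            # worst case: gantry running flat out
            if mu_per_deg < limits.mu_per_degree_min - 1e-9:
                out.append(Violation(s, "mu_floor", mu_per_deg,
                                     limits.mu_per_degree_min,
                                     "MU per degree below controller floor"))
    return out


def invert_max_speed(mu_threshold: float, travel: float, dr_max: float) -> float:
    """Recover an axis speed limit from a measured bin-transition threshold.

    ``mu_threshold`` is the smallest MU setting for which a fixed-travel
    dynamic field still delivers at the top dose-rate bin; at that point the
    axis is moving exactly at its maximum, so
    ``v_max = dr_max * travel / mu_threshold`` with ``dr_max`` in MU/s.
    """
    if mu_threshold <= 0 or travel <= 0 or dr_max <= 0:
        raise ValueError("all inputs must be > 0")
    return (dr_max / 60.0) * travel / mu_threshold
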