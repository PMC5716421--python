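"""Seedable end-to-end fixtures: plan + simulated image(s) + expected layout.

``make_fixture`` is the glue that makes every analysis testable without a
linac: it generates a named test plan, simulates its delivery with the
configured error model, renders the detector image(s) and returns an
analyzer-ready bundle.  Identical (name, config, seed) inputs produce
identical outputs.
"""

from __future__ import annotations

from typing import Optional

from .generators import (
    gen_dr_change_test,
    gen_dr_gs_strip_test,
    gen_mlc_speed_strip_test,
    gen_picket_fence,
    gen_reversal_test,
    gen_speed_limit_test,
    gen_utility_fields,
)
from .io import RunConfig
from .simulator import ErrorModel, render_fluence, simulate

__all__ = ["FIXTURE_NAMES", "make_fixture", "DEFAULT_PICKET_ERRORS"]

DEFAULT_PICKET_ERRORS = (
    {"leaf_pair": 20, "widen_to": 0.15},
    {"leaf_pair": 25, "shift": 0.05},
)

FIXTURE_NAMES = (
    "picket_fence",
    "picket_fence_errors",
    "dr_gs_strips",
    "mlc_speed_strips",
    "reversal",
    "dr_change_increase",
    "dr_change_decrease",
    "gravity",
    "open_field",
    "speed_limit_mlc",
    "speed_limit_jaw",
    "speed_limit_gantry",
)


def _render(plan, cfg: RunConfig, seed: int, dt: float = 0.01,
            errors: Optional[ErrorModel] = None):
    err = errors if errors is not None else cfg.error_model
    trace = simulate(plan, cfg.limits, err, dt=dt)
    return trace, render_fluence(trace, cfg.detector, err, seed=seed)


def make_fixture(test_name: str, config: Optional[RunConfig] = None, seed: int = 0) -> dict:
    """Build the named test bundle; see ``FIXTURE_NAMES`` for valid names."""
    cfg = config or RunConfig()
    lim = cfg.limits
    out: dict = {"name": test_name, "seed": seed}

    if test_name in ("picket_fence", "picket_fence_errors"):
        errors = DEFAULT_PICKET_ERRORS if test_name.endswith("errors") else ()
        plan = gen_picket_fence(lim, errors=errors)
        trace, img = _render(plan, cfg, seed)
        out.update(plan=plan, trace=trace, image=img, expected={
            "picket_positions_cm": [s.x_start for s in plan.strip_specs],
            "picket_width_cm": plan.strip_specs[0].width
            if plan.strip_specs else 0.1,
            "errors": [dict(e) for e in errors],
        })
    elif test_name == "dr_gs_strips":
        plan = gen_dr_gs_strip_test(lim)
        ref = gen_utility_fields("open_field", lim, field_size=25.0,
                                 mu=plan.strip_specs[0].planned_mu + 2.5)
        trace, img = _render(plan, cfg, seed)
        _, ref_img = _render(ref, cfg, seed + 1)
        out.update(plan=plan, trace=trace, image=img, reference_image=ref_img,
                   expected={"strips": [
                       {"index": s.index, "dr_factor": s.dr_factor,
                        "gs_factor": s.gs_factor} for s in plan.strip_specs]})
    elif test_name == "mlc_speed_strips":
        plan = gen_mlc_speed_strip_test(lim)
        # uniform sweep fluence: gap * DR_max / v_max MU everywhere in-field
        g = 0.8
        ref = gen_utility_fields("open_field", lim, field_size=25.0,
                                 mu=g * lim.dr_max_mu_s / lim.mlc_speed_max)
        trace, img = _render(plan, cfg, seed)
        _, ref_img = _render(ref, cfg, seed + 1)
        out.update(plan=plan, trace=trace, image=img, reference_image=ref_img,
                   expected={"strips": [
                       {"index": s.index, "mlc_speed_factor": s.mlc_speed_factor,
                        "dr_factor": s.dr_factor} for s in plan.strip_specs]})
    elif test_name == "reversal":
        plans = gen_reversal_test(lim)
        test_plan, ref_plan = plans[0], plans[-1]
        trace, img = _render(test_plan, cfg, seed)
        _, ref_img = _render(ref_plan, cfg, seed + 1,
                             errors=ErrorModel(noise_sigma=cfg.error_model.noise_sigma))
        out.update(plans=plans, plan=test_plan, trace=trace, image=img,
                   reference_image=ref_img,
                   expected={"junctions_cm": [s.x_end for s in test_plan.strip_specs],
                             "traversals": [s.traversal_count
                                            for s in test_plan.strip_specs]})
    elif test_name in ("dr_change_increase", "dr_change_decrease"):
        direction = test_name.rsplit("_", 1)[1]
        test_plan, ref_plan = gen_dr_change_test(direction, lim)
        trace, img = _render(test_plan, cfg, seed)
        _, ref_img = _render(ref_plan, cfg, seed + 1,
                             errors=ErrorModel(noise_sigma=cfg.error_model.noise_sigma))
        out.update(plan=test_plan, reference_plan=ref_plan, trace=trace,
                   image=img, reference_image=ref_img,
                   expected={"junctions_cm": [s.x_end
                                              for s in test_plan.strip_specs[:-1]],
                             "dr_factors": [s.dr_factor
                                            for s in test_plan.strip_specs]})
    elif test_name == "gravity":
        plan = gen_utility_fields("dmlc_gravity", lim)
        trace, img = _render(plan, cfg, seed)
        out.update(plan=plan, trace=trace, image=img,
                   expected={"interior_fluence_mu":
                             lim.dr_max_mu_s * 1.0 / 0.74})
    elif test_name == "open_field":
        plan = gen_utility_fields("open_field", lim)
        trace, img = _render(plan, cfg, seed)
        out.update(plan=plan, trace=trace, image=img,
                   expected={"interior_fluence_mu": plan.total_mu})
    elif test_name.startswith("speed_limit_"):
        axis = test_name.rsplit("_", 1)[1]
        travel = 180.0 if axis == "gantry" else 10.0
        plan = gen_speed_limit_test(axis, travel, lim)
        out.update(plan=plan, expected={"mu": plan.total_mu})
    else:
        raise ValueError(
            f"unknown test {test_name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return out
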