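"""Shared fixtures: expensive simulations are session-scoped and noiseless."""

import numpy as np
import pytest

from vmatqa import DetectorModel, MachineLimits, render_fluence, simulate
from vmatqa.generators import (
    gen_dr_gs_strip_test,
    gen_mlc_speed_strip_test,
    gen_picket_fence,
    gen_reversal_test,
    gen_utility_fields,
)

PICKETS = [-9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0]
ERRORS = ({"leaf_pair": 20, "widen_to": 0.15}, {"leaf_pair": 25, "shift": 0.05})


@pytest.fixture(scope="session")
def limits():
    return MachineLimits()


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def fence_image(limits, detector):
    plan = gen_picket_fence(limits)
    return plan, render_fluence(simulate(plan, limits), detector)


@pytest.fixture(scope="session")
def fence_image_static(limits, detector):
    plan = gen_picket_fence(limits, arc=None, static_angle=0.0)
    return plan, render_fluence(simulate(plan, limits), detector)


@pytest.fixture(scope="session")
def error_fence_image(limits, detector):
    plan = gen_picket_fence(limits, errors=ERRORS)
    return plan, render_fluence(simulate(plan, limits), detector)


@pytest.fixture(scope="session")
def open_field_image(limits, detector):
    def build(mu):
        plan = gen_utility_fields("open_field", limits, mu=mu)
        return render_fluence(simulate(plan, limits), detector)
    return build


@pytest.fixture(scope="session")
def drgs_bundle(limits, detector, open_field_image):
    plan = gen_dr_gs_strip_test(limits)
    img = render_fluence(simulate(plan, limits), detector)
    ref = open_field_image(plan.strip_specs[0].planned_mu + 2.5)
    return plan, img, ref


@pytest.fixture(scope="session")
def mlc_speed_bundle(limits, detector, open_field_image):
    plan = gen_mlc_speed_strip_test(limits)
    img = render_fluence(simulate(plan, limits), detector)
    ref = open_field_image(0.8 * limits.dr_max_mu_s / limits.mlc_speed_max)
    return plan, img, ref


@pytest.fixture(scope="session")
def reversal_plans(limits):
    return gen_reversal_test(limits)


@pytest.fixture(scope="session")
def reversal_reference_profile(reversal_plans, limits, detector):
    ref = reversal_plans[-1]
    # sample the slow reference so each step moves the leaves the same
    # distance as the fast delivery at dt = 0.004 s (discretisation cancels
    # in the ratio)
    img = render_fluence(simulate(ref, limits, dt=0.004 * 2.0 / 0.36), detector)
    return img.profile((0.25, 0.75))


def normalized_reversal_profile(plan, limits, detector, ref_profile, errors=None):
    img = render_fluence(simulate(plan, limits, errors, dt=0.004), detector)
    prof = img.profile((0.25, 0.75))
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = 100.0 * prof / ref_profile
    norm *= 100.0 / np.nanmedian(norm)
    return norm, img.x
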