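"""Shared fixtures: a desk-scale phantom and registration-based course runs.

The heavy pieces (deformable registrations, processed courses) are
session-scoped so unit, property and acceptance tests share one computation.
Grid and course sizes are reduced from the package defaults to keep the
whole suite desk-fast; docs/methods.md states the sizes used.
"""

from __future__ import annotations

import numpy as np
import pytest

from adaptrt.dose_mapping import accumulate, daily_dose
from adaptrt.phantom import (
    CourseSimulator,
    CourseTruth,
    PhantomConfig,
    make_plan_phantom,
    simulate_course,
)
from adaptrt.registration import RegistrationParams, register
from adaptrt.reporting import process_course

FAST_SHAPE = (48, 72, 72)
FAST_SPACING = (2.5, 2.5, 2.5)


def fast_config(**overrides) -> PhantomConfig:
    kw = dict(shape=FAST_SHAPE, spacing=FAST_SPACING, body_semiaxes=(55.0, 80.0, 85.0))
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def plan_bundle():
    """Default fast phantom plan: (image, plan context, dose grid)."""
    return make_plan_phantom(fast_config(), seed=1)


@pytest.fixture(scope="session")
def translation_case(plan_bundle):
    """A daily volume that is the plan anatomy rigidly shifted +5 mm in x."""
    img, plan, dose = plan_bundle
    cfg = fast_config()
    truth = CourseTruth(
        n_fractions=1, parotid_drift_mm_per_fraction=0.0,
        target_shrink_per_fraction=0.0, body_shrink_per_fraction=0.0,
        setup_sigma_mm=0.0, rotation_sigma_deg=0.0, noise_sigma=3.0, seed=2,
    )
    sim = CourseSimulator(cfg, truth, model_seed=1)
    truth.setup_translations = np.array([[0.0, 0.0, 5.0]])
    daily = sim.daily_volume(img, 1)
    dvf = register(img, daily, RegistrationParams())
    return {"daily": daily, "dvf": dvf, "shift": np.array([0.0, 0.0, 5.0])}


@pytest.fixture(scope="session")
def parotid_shift_case(plan_bundle):
    """A daily volume with a 4 mm medial parotid drift (8 x 0.5 mm/fraction)."""
    img, plan, dose = plan_bundle
    cfg = fast_config()
    truth = CourseTruth(
        n_fractions=8, parotid_drift_mm_per_fraction=0.5,
        target_shrink_per_fraction=0.0, body_shrink_per_fraction=0.0,
        setup_sigma_mm=0.0, rotation_sigma_deg=0.0, noise_sigma=3.0, seed=2,
    )
    sim = CourseSimulator(cfg, truth, model_seed=1)
    daily = sim.daily_volume(img, 8)
    truth_dvf = sim.truth_dvf(img, 8)
    dvf = register(img, daily, RegistrationParams())
    return {"daily": daily, "dvf": dvf, "truth_dvf": truth_dvf}


# ---------------------------------------------------------------------------
# Registration-based course runs
# ---------------------------------------------------------------------------

N_ZERO_FRACTIONS = 5
DRIFT_FRACTIONS = 12


@pytest.fixture(scope="session")
def zero_course(plan_bundle):
    """Zero drift, zero setup error, zero noise: daily volumes == plan."""
    img, plan, dose = plan_bundle
    truth = CourseTruth(
        n_fractions=N_ZERO_FRACTIONS, parotid_drift_mm_per_fraction=0.0,
        target_shrink_per_fraction=0.0, body_shrink_per_fraction=0.0,
        setup_sigma_mm=0.0, rotation_sigma_deg=0.0, noise_sigma=0.0, seed=4,
    )
    dailies, dvfs = simulate_course(img, truth, fast_config(), model_seed=1)
    return {"dailies": dailies, "truth_dvfs": dvfs, "truth": truth}


@pytest.fixture(scope="session")
def zero_course_report(plan_bundle, zero_course):
    img, plan, dose = plan_bundle
    return process_course(
        img, plan, dose, zero_course["dailies"], study="zero-drift",
    )


@pytest.fixture(scope="session")
def drift_course(drift_plan_bundle):
    """Parotid drift course engineered to cross its DE_0 mid-course.

    Parotids are placed farther laterally (planned Dmean ~17.5 Gy) so the
    0.5 mm/fraction medial drift pushes the projected Dmean over 20 Gy
    around fraction 6 of 12.  Drift is the only anatomical change (no setup
    jitter) so the ground-truth crossing is clean; image noise stays on.
    Ground-truth DP trajectories come from the analytic truth fields.
    """
    img, plan, dose = drift_plan_bundle
    cfg = fast_config(parotid_center_x=69.0)
    truth = CourseTruth(
        n_fractions=DRIFT_FRACTIONS, parotid_drift_mm_per_fraction=0.5,
        target_shrink_per_fraction=0.0, body_shrink_per_fraction=0.0,
        setup_sigma_mm=0.0, rotation_sigma_deg=0.0, noise_sigma=3.0, seed=5,
    )
    dailies, dvfs = simulate_course(img, truth, cfg, model_seed=1)

    parotid = plan.structure("parotid_L")
    samples = [daily_dose(dose, dvf, parotid) for dvf in dvfs]
    day, cum = [], []
    for k in range(1, len(samples) + 1):
        acc = accumulate(samples[:k], plan.total_fractions)
        day.append(float(acc.day.mean()))
        cum.append(float(acc.cumulative.mean()))
    return {
        "dailies": dailies,
        "truth_dvfs": dvfs,
        "truth": truth,
        "truth_dmean_day": np.array(day),
        "truth_dmean_sum": np.array(cum),
    }


@pytest.fixture(scope="session")
def drift_plan_bundle():
    return make_plan_phantom(fast_config(parotid_center_x=69.0), seed=1)


@pytest.fixture(scope="session")
def drift_course_report(drift_plan_bundle, drift_course):
    """The registration-based pipeline run over the drifting-parotid course."""
    img, plan, dose = drift_plan_bundle
    return process_course(
        img, plan, dose, drift_course["dailies"], study="drift",
    )
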