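import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vmadapt.cohort import LearnerParams, default_cohort_config, simulate_cohort
from vmadapt.protocol import build_schedule, default_design


@pytest.fixture(scope="session")
def exp1_design():
    return default_design("exp1")


@pytest.fixture(scope="session")
def exp1_schedule(exp1_design):
    return build_schedule(exp1_design, seed=1)


@pytest.fixture
def noise_free_params():
    """Deterministic two-process learner (no motor or report noise)."""
    return LearnerParams(
        eta_explicit=0.2,
        A_implicit=0.98,
        B_implicit=0.05,
        sigma_motor=0.0,
        sigma_report=0.0,
        explicit_cap_deg=60.0,
        rt_mean_s=0.5,
        rt_sd_s=0.0,
        mt_mean_s=0.3,
        mt_sd_s=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small fast exp1-like cohort without rendered trajectories."""
    cfg = default_cohort_config("exp1", n_per_group=4, seed=11, render_trajectories=False)
    return simulate_cohort(cfg)
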