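import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import condlearn as cl

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


MID_THETA = {
    "rw": {"alpha_ctx": 0.3, "alpha_cue": 0.3, "beta_us": 0.3,
           "beta_nous": 0.3, "g": 5.0},
    "crw": {"alpha_ctx": 0.3, "alpha_cue": 0.3, "alpha_cfg": 0.3,
            "beta_us": 0.3, "beta_nous": 0.3, "g": 5.0},
    "pearce": {"alpha_pat": 0.3, "beta_us": 0.3, "beta_nous": 0.3,
               "d": 2.0, "g": 5.0},
}


@pytest.fixture(scope="session")
def designs():
    """One deterministic design per group."""
    return {g: cl.build_design(g, 1234) for g in ("control", "deepened", "super")}


@pytest.fixture(scope="session")
def mid_theta():
    """Mid-box teacher parameters (all learning rates 0.3, g = 5, d = 2)."""
    return {m: dict(th) for m, th in MID_THETA.items()}


@pytest.fixture(scope="session")
def rw_teacher_data(designs, mid_theta):
    """(design, responses) sampled from a mid-box RW teacher."""
    design = designs["super"]
    responses = cl.simulate_responses("rw", mid_theta["rw"], design, 99)
    return design, responses
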