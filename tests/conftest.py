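import warnings

import numpy as np
import pytest

from ipwmed import (
    DesignSpec,
    assign_design,
    default_causal_spec,
    default_config,
    generate_cohort,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def spec():
    return default_causal_spec()


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def small_config():
    """Default structural model at a size suited for unit tests."""
    return default_config(n=6000, seed=123, missing_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return assign_design(generate_cohort(small_config), small_config)


@pytest.fixture(scope="session")
def discrete_config():
    """Fully discrete structural model with explicit (uncalibrated) intercepts
    and explicit outcome coefficients (no solved targets)."""
    from ipwmed import OutcomeSpec

    return default_config(
        include_c3=False,
        include_l2=False,
        exposure_prevalence=0.5,
        mediator_marginals=None,
        coef_c_on_x=(("intercept", 0.0), ("c1", 0.7), ("c2", -0.5)),
        coef_on_l1=(("intercept", -1.0), ("x", 0.6), ("c1", 0.3), ("c2", 0.4)),
        coef_on_m_non_centre=(
            ("intercept", 0.2), ("x", -0.4), ("c1", -0.3), ("c2", 0.2), ("l1", -0.3),
        ),
        coef_on_m_centre=(
            ("intercept", -0.1), ("x", -0.6), ("c1", -0.5), ("c2", 0.3), ("l1", -0.4),
        ),
        outcomes=(
            (
                "y_ext",
                OutcomeSpec(
                    coef_x=0.12,
                    coef_m=(("non_centre", -0.03), ("centre", -0.08)),
                    interaction=(("centre", -0.10),),
                    coef_c=(("c1", 0.10), ("c2", 0.25)),
                    coef_l=(("l1", 0.25),),
                    noise_sd=0.9,
                ),
            ),
            (
                "y_voc",
                OutcomeSpec(
                    coef_x=-0.25,
                    coef_m=(("non_centre", 0.10), ("centre", 0.03)),
                    coef_c=(("c1", -0.10), ("c2", -0.20)),
                    coef_l=(("l1", -0.10),),
                    noise_sd=0.9,
                ),
            ),
        ),
    )
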