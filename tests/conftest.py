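import numpy as np
import pytest

from growthmix.models import (
    Family,
    GrowthParameters,
    ModelSpec,
    ResidualStructure,
)

SYMPTOM_TIMES = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)


@pytest.fixture(scope="session")
def gbtm2_spec():
    """Well-separated 2-class quadratic group-based trajectory model."""
    return ModelSpec(
        family=Family.GBTM,
        n_classes=2,
        poly_order_per_class=(2, 2),
        residual_structure=ResidualStructure.FIXED,
        visit_times=SYMPTOM_TIMES,
    )


@pytest.fixture(scope="session")
def gbtm2_params():
    return GrowthParameters(
        class_proportions=np.array([0.4, 0.6]),
        growth_coefficients=(
            np.array([3.0, -0.35, 0.011]),
            np.array([9.8, -0.9, 0.03]),
        ),
        re_covariance=None,
        residual_variances=4.0,
    )


@pytest.fixture(scope="session")
def gbtm2_dataset(gbtm2_spec, gbtm2_params):
    from growthmix.simulate import generate_from_model

    sim = generate_from_model(gbtm2_spec, gbtm2_params, 400, seed=11)
    return sim.outcomes["outcome"], sim.true_classes["outcome"]


@pytest.fixture(scope="session")
def small_complete_cohort():
    """Complete-data synthetic cohort (no missingness), 150 subjects."""
    from growthmix.simulate import default_config, generate_cohort

    cfg = default_config(n_subjects=150, seed=7)
    for name in cfg.missing_rates:
        cfg.missing_rates[name] = [0.0] * len(cfg.missing_rates[name])
    return generate_cohort(cfg)
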