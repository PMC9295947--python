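import numpy as np
import pytest

from placenorm import CohortConfig, evaluate_model, fit_model, simulate_cohort
from placenorm.reference import T2STAR_SIGMOID

UN_PARAMS, UN_SD = T2STAR_SIGMOID["UN"]


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale synthetic cohort (316 subjects) under default conditions."""
    return simulate_cohort(CohortConfig(seed=12345))


@pytest.fixture(scope="session")
def un_cohort():
    """Uncomplicated-only cohort, roughly the study's ~560 UN scan count."""
    return simulate_cohort(CohortConfig(n_subjects=250, group_probs=(1.0, 0.0, 0.0), seed=2024))


@pytest.fixture(scope="session")
def un_reference_fit(un_cohort):
    """Sigmoid reference fit to the uncomplicated cohort."""
    return fit_model(un_cohort["ga_weeks"], un_cohort["t2star_ms"], "sigmoid", random_state=0)


@pytest.fixture(scope="session")
def un_sigmoid_sample():
    """n=500 draws from the UN sigmoid with Gaussian residuals, GA ~ U(11, 38)."""
    rng = np.random.default_rng(42)
    t = rng.uniform(11.0, 38.0, 500)
    y = evaluate_model("sigmoid", UN_PARAMS, t) + rng.normal(0.0, UN_SD, 500)
    return t, y
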