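import numpy as np
import pytest

from wetlandghg.gapfill import PredictorMatrix
from wetlandghg.synth import (
    GapConfig,
    SiteScenario,
    apply_gaps,
    generate_fluxes,
    generate_met,
)


@pytest.fixture(scope="session")
def mature_scenario():
    """One fully vegetated site-year (the recovery-test condition)."""
    return SiteScenario(site_id="MAT", years=1, vegetation_trajectory=(1.0,), seed=3)


@pytest.fixture(scope="session")
def mature_met(mature_scenario):
    return generate_met(mature_scenario)


@pytest.fixture(scope="session")
def mature_truth(mature_scenario, mature_met):
    return generate_fluxes(mature_met, mature_scenario)


@pytest.fixture(scope="session")
def gapped_30pct(mature_truth, mature_met):
    """Observation with 30% random gaps on both gases."""
    return apply_gaps(mature_truth, mature_met, GapConfig(random_rate=0.3, seed=4))


@pytest.fixture(scope="session")
def predictor_matrix(mature_met):
    return PredictorMatrix.from_met(mature_met.data)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
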