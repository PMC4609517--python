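import numpy as np
import pytest
from hypothesis import settings

import activehia as ah

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rr_default() -> ah.RelativeRiskSet:
    return ah.RelativeRiskSet.default()


@pytest.fixture(scope="session")
def urban_profile() -> ah.CommunityProfile:
    return ah.generate_community(seed=1, size=20_000, profile_kind="urban")


@pytest.fixture(scope="session")
def suburban_profile() -> ah.CommunityProfile:
    return ah.generate_community(seed=1, size=10_000, profile_kind="suburban")


@pytest.fixture(scope="session")
def brrc_shift(urban_profile) -> ah.ExposureShift:
    """Urban-corridor walkability shift from the shipped fixture."""
    fx = ah.brrc_walkability_fixture()
    return ah.walkability_to_shift(
        ah.walkability_score(fx["before"]),
        ah.walkability_score(fx["after"]),
        urban_profile.baseline_exposure,
        fx["mapping"],
    )


@pytest.fixture(scope="session")
def tiny_profile() -> ah.CommunityProfile:
    """Three-age community for engine/oracle equivalence checks."""
    pop = np.zeros((101, 2))
    pop[50] = 500
    pop[60] = 300
    pop[70] = 200
    ages = ah.AGES.astype(float)
    mort = np.tile(np.clip(8e-5 * np.exp(0.088 * ages), 0, 0.6)[:, None], (1, 2))
    diseases = [
        ah.DiseaseSpec("hypertension", (-0.05, 0.004, 3e-5), annual_cost=1000.0),
        ah.DiseaseSpec("type2_diabetes", (-0.04, 0.0024, 1e-5), annual_cost=6600.0,
                       excess_mortality=0.005),
    ]
    exposure = ah.ExposureDistribution(0.4, 0.4, 0.2, 15.0)
    return ah.CommunityProfile("tiny", pop, mort, 0.0, diseases, exposure, 0.0)
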