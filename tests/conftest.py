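import numpy as np
import pytest
from hypothesis import settings

from atworkforce.domains import DOMAINS
from atworkforce.prevalence_model import (
    TransformedObservation,
    fit_mcmc,
    predict_prevalence,
    transform_prevalence,
)
from atworkforce.synthetic_world import SyntheticWorldConfig, generate_country_panel

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def observations_from_world(world, surveyed_only=True):
    """Exact transformed prevalences as model observations (no survey noise)."""
    countries = [c for c in world.countries if c.surveyed] if surveyed_only else world.countries
    return [
        TransformedObservation(
            country_id=c.country_id,
            domain=d,
            y=transform_prevalence(world.true_prevalence[(c.country_id, d)]),
            median_age=c.median_age,
            hdi=c.hdi,
        )
        for c in countries
        for d in DOMAINS
    ]


@pytest.fixture(scope="session")
def recovery_world():
    """28 surveyed + 161 unsurveyed countries, residual sd 0.02, seed 3."""
    return generate_country_panel(SyntheticWorldConfig(seed=3))


@pytest.fixture(scope="session")
def recovery_fit(recovery_world):
    """Mixed-model fit on the 140 surveyed-country observations."""
    obs = observations_from_world(recovery_world)
    assert len(obs) == 140
    return fit_mcmc(obs, seed=5, n_iter=8_000, burn_in=2_000)


@pytest.fixture(scope="session")
def coverage_predictions(recovery_world, recovery_fit):
    """Posterior predictive prevalences for the 161 unsurveyed countries."""
    unsurveyed = [c for c in recovery_world.countries if not c.surveyed]
    assert len(unsurveyed) == 161
    return predict_prevalence(recovery_fit, unsurveyed, seed=17)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
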