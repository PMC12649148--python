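import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from lbb import (  # noqa: E402
    MCMCConfig,
    default_recovery_scenario,
    scenario_priors,
    simulate_catch,
)
from lbb.datasets import load_survey_assessment, load_survey_priors  # noqa: E402


@pytest.fixture(scope="session")
def survey_priors():
    return load_survey_priors()


@pytest.fixture(scope="session")
def survey_assessment():
    return load_survey_assessment()


@pytest.fixture(scope="session")
def fished_lf():
    """One simulated catch from the canonical moderately fished scenario."""
    return simulate_catch(default_recovery_scenario(seed=7))


@pytest.fixture(scope="session")
def fished_priors():
    return scenario_priors(default_recovery_scenario().true_state)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Scaled-down sampler settings for unit tests."""
    return MCMCConfig(chains=2, iterations=4000, thin=5, seed=11)


@pytest.fixture(scope="session")
def fitted_posterior(fished_lf, fished_priors, fast_mcmc):
    """A reusable small fit of the canonical scenario."""
    from lbb import fit_lbb

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_lbb(fished_lf, priors=fished_priors, mcmc=fast_mcmc)
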