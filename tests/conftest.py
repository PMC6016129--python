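import numpy as np
import pandas as pd
import pytest

from sescra.exposure import ExposureProfile, with_gamma
from sescra.risk import load_default_risk_config
from sescra.synthetic import SyntheticScenario, generate_survey
from sescra import published


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=20150)


@pytest.fixture(scope="session")
def big_survey(scenario):
    """Large synthetic survey for law-of-large-numbers checks."""
    return generate_survey(scenario, 100_000)


@pytest.fixture(scope="session")
def survey_10k(scenario):
    return generate_survey(scenario, 10_000)


@pytest.fixture(scope="session")
def registry_riskfns():
    return load_default_risk_config()


@pytest.fixture(scope="session")
def published_profiles():
    """Six (SES, sex) exposure profiles built from the published
    population statistics (no age-band resolution)."""
    profiles = []
    for (ses, sex), mean in published.MEAN_GPD_DRINKERS.items():
        p_abst = published.P_LIFETIME_ABSTAINER[(ses, sex)]
        p_cur = published.P_CURRENT_DRINKER[(ses, sex)]
        profiles.append(
            with_gamma(
                ExposureProfile(
                    ses=ses, sex=sex, age_band=None,
                    p_abstainer=p_abst,
                    p_former=1.0 - p_abst - p_cur,
                    p_current=p_cur,
                    p_binge=published.P_BINGE_DRINKER[(ses, sex)],
                    mean_gpd=mean,
                )
            )
        )
    return profiles


@pytest.fixture(scope="session")
def published_populations():
    return {k: float(v) for k, v in published.POPULATION_15PLUS.items()}
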