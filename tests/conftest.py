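import pytest
from hypothesis import HealthCheck, settings

from bayesrisk import (
    build_risk_table,
    load_hail_cases,
    load_hail_clinical,
    load_hail_population,
    load_hail_published_posteriors,
)

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hail_cases():
    return load_hail_cases()


@pytest.fixture(scope="session")
def hail_clinical():
    return load_hail_clinical()


@pytest.fixture(scope="session")
def hail_pop():
    return load_hail_population()


@pytest.fixture(scope="session")
def hail_published():
    return load_hail_published_posteriors()


@pytest.fixture(scope="session")
def hail_risk_table(hail_cases, hail_pop, hail_published):
    return build_risk_table(
        hail_cases, hail_pop, prior="auto", published_posteriors=hail_published
    )
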