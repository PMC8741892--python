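import numpy as np
import pytest
from hypothesis import settings

import cureaft as ca

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper80_design():
    return ca.ModelDesign(location_terms=("high",))


@pytest.fixture(scope="session")
def paper80_cohort():
    """One medium cohort from the default generative preset."""
    return ca.generate_cohort(ca.paper80_config(n=2000, seed=42))


@pytest.fixture(scope="session")
def paper80_fit(paper80_cohort, paper80_design):
    return ca.fit(paper80_cohort.records, paper80_design, seed=42)


@pytest.fixture()
def tiny_cohort():
    """Hand-built: event at 1, censored at 2, event at 3."""
    return [
        ca.SurvivalRecord(1.0, 1),
        ca.SurvivalRecord(2.0, 0),
        ca.SurvivalRecord(3.0, 1),
    ]


def random_cohort(n, seed, censor_at=4.0):
    """Small unstructured cohort for likelihood identities."""
    rng = np.random.default_rng(seed)
    t = np.exp(rng.normal(0.5, 0.8, n))
    c = rng.uniform(0.2, censor_at, n)
    event = t <= c
    obs = np.where(event, t, c)
    return [
        ca.SurvivalRecord(float(obs[i]), int(event[i]), {"x": float(rng.normal())})
        for i in range(n)
    ]
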