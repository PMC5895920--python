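import logging

import pytest

import adaudit as ad
from adaudit.world import (
    ConditionConfig,
    InterestConfig,
    WorldConfig,
    generate_world,
)

# degenerate-cell and share>1 warnings are expected in several tests
logging.getLogger("adaudit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def us_snapshot():
    """Packaged September-2016 US-wide audience totals."""
    return ad.us_audience_2016()


@pytest.fixture(scope="session")
def us_taxonomy():
    return ad.us_interest_taxonomy()


@pytest.fixture
def small_world():
    """A 3-state world with one marker, one placebo, and a planted lift."""
    config = WorldConfig(
        conditions=[ConditionConfig(name="obesity", mu=-1.2, beta=0.3, sigma=0.1)],
        interests=[
            InterestConfig(
                name="plus-size clothing",
                role="marker",
                condition="obesity",
                theta=-3.0,
                lam=0.3,
            ),
            InterestConfig(name="technology", role="placebo", theta=-1.0, kappa=0.2),
            InterestConfig(name="Facebook", role="reference", theta=-0.5, kappa=0.3),
        ],
        n_states=3,
        state_populations=500_000,
        rho=0.4,
        pairwise_lift={frozenset(("plus-size clothing", "technology")): 1.5},
        seed=11,
    )
    return generate_world(config)


@pytest.fixture
def health_rows():
    return [
        ("AL", "obesity", 0.36),
        ("AK", "obesity", 0.30),
        ("AZ", "obesity", 0.28),
    ]
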