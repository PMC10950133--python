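import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hacua import LifeTable, fixture_bundle, run_all_arms

settings.register_profile(
    "hacua",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("hacua")


@pytest.fixture(scope="session")
def bundle():
    return fixture_bundle(seed=0)


@pytest.fixture(scope="session")
def male_inputs(bundle):
    return (
        bundle.params["male"],
        bundle.transition_models["male"],
        bundle.life_tables["male"],
    )


@pytest.fixture(scope="session")
def female_inputs(bundle):
    return (
        bundle.params["female"],
        bundle.transition_models["female"],
        bundle.life_tables["female"],
    )


@pytest.fixture(scope="session")
def male_results(male_inputs):
    return run_all_arms(*male_inputs)


@pytest.fixture(scope="session")
def female_results(female_inputs):
    return run_all_arms(*female_inputs)


def flat_life_table(q: float, start: int = 55, end: int = 110, gender: str = "male") -> LifeTable:
    """Life table with a constant annual death probability (horizon closed)."""
    qs = np.full(end - start + 1, q, dtype=float)
    qs[-1] = 1.0
    return LifeTable(gender=gender, start_age=start, q=qs)
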