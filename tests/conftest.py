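import pytest

from agestage.cohort import Cohort, IndividualRecord
from agestage.simulate import SyntheticCohortSpec, generate_cohort


def make_toy_cohort() -> Cohort:
    """Four-egg cohort: two preadult deaths as L1 on day 6, one male dying
    day 30, one female dying day 35 laying 3+2+1 eggs on days 25-27."""
    preadult = {"egg": 0, "L1": 5, "L2": 8, "L3": 11, "L4": 14, "pupa": 17}
    return Cohort(individuals=[
        IndividualRecord("d1", "u", {"egg": 0, "L1": 5}, death_age=6),
        IndividualRecord("d2", "u", {"egg": 0, "L1": 5}, death_age=6),
        IndividualRecord("m1", "m", {**preadult, "male_adult": 24}, death_age=30),
        IndividualRecord("f1", "f", {**preadult, "female_adult": 23}, death_age=35,
                         fecundity={25: 3, 26: 2, 27: 1}),
    ])


@pytest.fixture
def toy_cohort() -> Cohort:
    return make_toy_cohort()


@pytest.fixture(scope="session")
def default_spec() -> SyntheticCohortSpec:
    return SyntheticCohortSpec(seed=42, n_01=300)


@pytest.fixture(scope="session")
def synthetic_cohort(default_spec) -> Cohort:
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    return generate_cohort(SyntheticCohortSpec(seed=7, n_01=50))
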