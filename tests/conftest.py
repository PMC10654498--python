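import pytest
from hypothesis import HealthCheck, settings

import gapdesign as gd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def seed_population() -> list[str]:
    """A 100-molecule synthetic seed population shared across module tests."""
    return gd.make_seed_population(gd.FixtureConfig(n_molecules=100, seed=7))


@pytest.fixture(scope="session")
def large_population() -> list[str]:
    """A 500-molecule population for distributional checks."""
    return gd.make_seed_population(gd.FixtureConfig(n_molecules=500, seed=11))


@pytest.fixture(scope="session")
def labeled_records(seed_population):
    """PropertyRecords with toy-oracle gaps for the shared population."""
    oracle = gd.ToyGapOracle()
    return [
        gd.PropertyRecord(
            smiles=s, gap=oracle(gd.parse_smiles(s)), generation=0, split="train"
        )
        for s in seed_population
    ]
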