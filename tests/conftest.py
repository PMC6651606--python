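import pytest

from upsdiverge.synthetic_data import EvolveParams, brassicaceae_ladder, simulate_genomes


@pytest.fixture(scope="session")
def truth_lossless():
    """Full 13-species simulation with no gene loss (exact-recovery regime)."""
    ladder = brassicaceae_ladder(seed=11)
    params = EvolveParams(seed=11, birth_rate=0.4, death_rate=0.0)
    return simulate_genomes(ladder, params)


@pytest.fixture(scope="session")
def ladder():
    return brassicaceae_ladder(seed=11)


@pytest.fixture(scope="session")
def truth_small():
    """Single-clade simulation (no Poaceae role) for cheap unit tests."""
    ladder = brassicaceae_ladder(seed=5, second_family=False)
    params = EvolveParams(
        seed=5, birth_rate=0.3, death_rate=0.0,
        families={"FBX": 3, "RING": 3, "Skp1": 2},
    )
    return simulate_genomes(ladder, params)
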