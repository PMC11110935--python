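import pytest

from introtrio import TaxonScheme
from introtrio.simulate import SimParams, simulate_dataset, triplet_record_from_sim


@pytest.fixture(scope="session")
def scheme() -> TaxonScheme:
    return TaxonScheme("Pa", "Pk", "Pe", "Oh")


@pytest.fixture(scope="session")
def intro_records():
    """Records from a genome with a strong B-C introgression pulse."""
    params = SimParams(gamma=0.3, n_genes=2000, seed=1234)
    return [triplet_record_from_sim(g) for g in simulate_dataset(params)]


@pytest.fixture(scope="session")
def null_records():
    """Records from a pure-ILS genome (no introgression)."""
    params = SimParams(gamma=0.0, n_genes=2000, seed=4321)
    return [triplet_record_from_sim(g) for g in simulate_dataset(params)]
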