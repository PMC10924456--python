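import numpy as np
import pytest

from genosig.blsom import BLSOMConfig, init_lattice, train
from genosig.ingest import concatenate_with_n, tile_windows
from genosig.kmer import build_dege_index, composition_matrix
from genosig.simulate import generate_community

COMMUNITY_SEED = 1


@pytest.fixture(scope="session")
def community():
    """The canonical 5-species synthetic community (100-kb windows)."""
    return generate_community(n_species=5, window_size=100_000, seed=COMMUNITY_SEED)


@pytest.fixture(scope="session")
def community_fragments(community):
    records = concatenate_with_n(community.records, min_length=community.window_size)
    fragments = []
    for rec in records:
        fragments.extend(tile_windows(rec, community.window_size))
    return fragments


@pytest.fixture(scope="session")
def community_matrix(community_fragments):
    """DegeTri composition matrix of the community fragments."""
    return composition_matrix(community_fragments, build_dege_index(3))


@pytest.fixture(scope="session")
def community_model(community_matrix):
    """Default-config BLSOM trained on the community matrix."""
    config = BLSOMConfig()
    return train(community_matrix, init_lattice(community_matrix, config), config)


def random_sequence(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    alphabet = np.array(list("ACGTN"))
    p = [(1 - n_prob) / 4] * 4 + [n_prob]
    return "".join(rng.choice(alphabet, size=length, p=p))
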