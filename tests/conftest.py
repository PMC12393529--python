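import numpy as np
import pytest

from symbiopan.io_formats import AssociationMatrix, GeneFamilyMatrix, SquareMatrix
from symbiopan.synthetic import (
    CophyloSimConfig,
    PangenomeSimConfig,
    simulate_cophylogeny,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def small_pangenome():
    """50-genome simulated matrix with all three family classes."""
    return simulate_pangenome(
        PangenomeSimConfig(
            n_genomes=50, n_core=20, n_accessory=100,
            unique_per_genome_mean=2.0, seed=7,
        )
    )


@pytest.fixture(scope="session")
def codiverged():
    """Pure-codivergence cophylogeny: isomorphic trees, one-to-one links."""
    return simulate_cophylogeny(CophyloSimConfig(n_hosts=8, seed=3))


@pytest.fixture
def toy_matrix():
    """3 families x 4 genomes with prevalences 4/4, 2/4, 1/4."""
    return GeneFamilyMatrix(
        families=["f_core", "f_acc", "f_uni"],
        genomes=["g1", "g2", "g3", "g4"],
        presence=np.array([[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 1, 0]]),
    )


def one_to_one_assoc(hosts, symbionts, perm=None):
    n = len(hosts)
    links = np.zeros((n, n), dtype=np.int8)
    perm = np.arange(n) if perm is None else np.asarray(perm)
    links[np.arange(n), perm] = 1
    return AssociationMatrix(list(hosts), list(symbionts), links)
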