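import numpy as np
import pytest

from gscortho.homology import Scoring, load_matrix
from gscortho.synthetic_data import CladeSimParams, simulate_clade

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def scoring():
    return Scoring()


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(len(AA20), size=n))


@pytest.fixture(scope="session")
def small_clade():
    """A 12-gene, 3-species clade with losses but no fragmentation."""
    return simulate_clade(
        CladeSimParams(
            n_genes=12,
            n_species=3,
            loss_prob=0.2,
            subst_rate=0.1,
            frag_break_rate=0.0,
            seed=11,
        )
    )
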