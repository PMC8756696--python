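import numpy as np
import pytest

from homeoprot import simulate
from homeoprot.homology import AlignmentHit, HomologPair


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        n_families=12, paralog_fraction=0.5, n_codons=60, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small synthetic proteome: (proteins, cds, truth, quant matrix)."""
    proteins, cds, truth = simulate.simulate_families(small_config)
    qm = simulate.simulate_quant(proteins, truth, small_config)
    return proteins, cds, truth, qm


def pairs_from_truth(truth, proteins=None, length=300):
    """HomologPair list straight from the generator's truth table (bypasses
    the alignment stage so classifier tests are isolated from pairing)."""
    by_id = {p.id: p for p in proteins} if proteins else {}

    def hit(a, b):
        la = len(by_id[a].sequence) if a in by_id else length
        lb = len(by_id[b].sequence) if b in by_id else length
        return AlignmentHit(a, b, 100.0, max(la, lb), la, lb, 1.0)

    return [
        HomologPair(p.id_a, p.id_b, p.relation, hit(p.id_a, p.id_b))
        for p in truth.pairs
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
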