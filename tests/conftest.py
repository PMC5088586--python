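import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from plastarch.genome_io import Feature, Plastome
from plastarch.synthetic import SimConfig, simulate_plastome


@pytest.fixture
def tiny_plastome():
    """100-bp circular genome: two genes, one intron, 30 bp intergenic.

    Layout: psbA [0,30)+, intron [30,40), rbcL [40,70)-, spacer [70,100).
    """
    seq = ("AT" * 50)[:100]
    feats = [
        Feature("psbA", "gene", "+", [(0, 30)]),
        Feature("psbA-intron", "intron", "+", [(30, 40)], {"intron_class": "IIA"}),
        Feature("rbcL", "gene", "-", [(40, 70)]),
    ]
    return Plastome("tiny", seq, True, feats)


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic quadripartite genome shared across tests."""
    return simulate_plastome(SimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_genome_no_ir():
    return simulate_plastome(SimConfig(seed=0, ir_length=0))
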