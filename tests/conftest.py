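import numpy as np
import pytest

from molforge.calculator import ToyForceField
from molforge.chemgraph import ChemicalGraph
from molforge.conformer import embed_initial, local_optimize


@pytest.fixture(scope="session")
def ethanol_graph():
    return ChemicalGraph.from_smiles("CCO")


@pytest.fixture(scope="session")
def ethanol_ff(ethanol_graph):
    return ToyForceField.from_graph(ethanol_graph)


@pytest.fixture(scope="session")
def ethanol_minimum(ethanol_graph, ethanol_ff):
    """Tightly optimized ethanol conformer (shared; treat as read-only)."""
    s0 = embed_initial(ethanol_graph, seed=1)
    return local_optimize(s0, ethanol_ff, f_max=1e-6)


@pytest.fixture(scope="session")
def water_minimum():
    g = ChemicalGraph.from_smiles("O")
    ff = ToyForceField.from_graph(g)
    conf = local_optimize(embed_initial(g, seed=1), ff, f_max=1e-7)
    return g, ff, conf


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
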