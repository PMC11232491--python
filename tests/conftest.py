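import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from swarmcite import PPINetwork, generate_study
from swarmcite.io import packaged_data


@pytest.fixture(scope="session")
def data_dir():
    return packaged_data("table1.tsv").parent


@pytest.fixture()
def triangle_network():
    net = PPINetwork()
    net.add_edge("A", "B")
    net.add_edge("B", "C")
    net.add_edge("A", "C")
    return net


@pytest.fixture()
def path7_network():
    """7-node path A-B-C-D-E-F-G."""
    net = PPINetwork()
    for a, b in zip("ABCDEF", "BCDEFG"):
        net.add_edge(a, b)
    return net


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared by counting/clustering tests."""
    return generate_study(
        n_proteins=30,
        n_pathways=3,
        n_probes=9,
        n_docs=600,
        n_tissues=3,
        coverage=0.9,
        seed=7,
    )
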