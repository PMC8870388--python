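import pytest

from mirnet.synthetic_data import SyntheticConfig, simulate_bundle
from mirnet.tables_io import OntologyDag


@pytest.fixture
def sibling_dag():
    """Two sibling terms A, B under a root C, all is_a (w=0.8)."""
    return OntologyDag(
        {"A": "term A", "B": "term B", "C": "root C"},
        [("A", "C", "is_a"), ("B", "C", "is_a")],
    )


@pytest.fixture
def chain_dag():
    """Chain D -> A -> C, all is_a."""
    return OntologyDag(
        {"D": "leaf D", "A": "mid A", "C": "root C"},
        [("D", "A", "is_a"), ("A", "C", "is_a")],
    )


@pytest.fixture
def diamond_dag():
    """Diamond: A below B and C, both below root R, all is_a."""
    return OntologyDag(
        {"A": "a", "B": "b", "C": "c", "R": "root"},
        [("A", "B", "is_a"), ("A", "C", "is_a"), ("B", "R", "is_a"), ("C", "R", "is_a")],
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic bundle at the default study conditions."""
    return simulate_bundle(SyntheticConfig(seed=0))
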