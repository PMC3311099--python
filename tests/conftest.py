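import networkx as nx
import pytest

from pedpaths import (
    add_virtual_root,
    encode_cpe,
    encode_nodecodes,
    example_pedigree,
)
from pedpaths.pedigree import VIRTUAL_ROOT_ID


@pytest.fixture(scope="session")
def ped8():
    """The eight-individual example pedigree."""
    return example_pedigree()


@pytest.fixture(scope="session")
def rooted8(ped8):
    return add_virtual_root(ped8)


@pytest.fixture(scope="session")
def table8(rooted8):
    return encode_cpe(rooted8)


@pytest.fixture(scope="session")
def nodecodes8(rooted8):
    return encode_nodecodes(rooted8)


def rooted_digraph(ped):
    """networkx digraph of a pedigree including the virtual root."""
    g = ped.to_networkx()
    g.add_node(VIRTUAL_ROOT_ID)
    for f in ped.founders:
        g.add_edge(VIRTUAL_ROOT_ID, f)
    return g


def dfs_paths(ped, a, b):
    """Independent oracle: all simple directed a->b paths, as id tuples."""
    g = ped.to_networkx()
    out = {tuple(p) for p in nx.all_simple_paths(g, a, b)}
    if a == b:
        out.add((a,))
    return out
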