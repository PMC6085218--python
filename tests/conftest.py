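"""Shared fixtures and independent oracles.

networkx serves as the independent graph oracle throughout: VF2
isomorphism for serializer round-trips, BFS distances for neighbor
shells, and all-pairs tree paths for longest-chain checks.  The
implementation under test never uses networkx itself.
"""

import networkx as nx
import pytest

from spices import LineSpec, SpicesMolecule, fixture_dmpc, parse


def to_networkx(mol: SpicesMolecule) -> nx.Graph:
    g = nx.Graph()
    for node in mol.nodes:
        g.add_node(node.index, name=node.name,
                   backbone_label=node.backbone_label,
                   tags=node.tags, part=node.part_index)
    g.add_edges_from(mol.bonds)
    return g


def molecules_isomorphic(a: SpicesMolecule, b: SpicesMolecule) -> bool:
    """Attribute-preserving graph isomorphism (names, labels, tags)."""
    def node_match(x, y):
        return (x["name"] == y["name"]
                and x["backbone_label"] == y["backbone_label"]
                and x["tags"] == y["tags"])
    return nx.is_isomorphic(to_networkx(a), to_networkx(b),
                            node_match=node_match)


def tree_longest_path_length(mol: SpicesMolecule) -> int:
    """Node count of the longest path of a tree, by exhaustive pairwise
    distances (paths in trees are unique, so shortest = only = longest)."""
    g = to_networkx(mol)
    assert nx.is_tree(g)
    best = 0
    for _src, dists in nx.all_pairs_shortest_path_length(g):
        best = max(best, max(dists.values()))
    return best + 1


@pytest.fixture
def dmpc():
    return parse(fixture_dmpc())


@pytest.fixture
def unit_line():
    return LineSpec((0.0, 0.0, 0.0), (10.0, 0.0, 0.0), 1.0)
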