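"""Graph-level queries on parsed SPICES molecules.

Everything here treats particles as opaque labeled vertices: frequencies,
breadth-first neighbor shells, connected-part extraction, and the
double-DFS ("double sweep") longest-chain search used to pick the main
chain for spatial tube construction.  The double sweep — DFS from the
first notation particle to the farthest particle A, then DFS from A to the
farthest particle B, returning the realized A→B path of the second DFS
tree — yields a true longest path on acyclic molecules; on cyclic ones the
result may be shorter than the global optimum, which is accepted behavior
for start-geometry purposes.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from typing import Optional

from .notation import SpicesMolecule, StructureError, TagError

__all__ = [
    "ChainPath",
    "particle_frequencies",
    "next_neighbors",
    "connected_parts",
    "longest_chain",
    "longest_chain_oriented",
]

#: Visited-state budget for the exhaustive oriented path search before
#: falling back to the DFS-tree heuristic (cycles can have exponentially
#: many simple paths).
DEFAULT_STATE_BUDGET = 10_000


@dataclass(frozen=True)
class ChainPath:
    """A simple path through a molecule, optionally tag-oriented.

    ``oriented`` is True when the path was fixed by a [START]/[END] tag
    pair, in which case the first node carries START and the last END.
    """

    node_indices: tuple[int, ...]
    oriented: bool = False

    def __len__(self) -> int:
        return len(self.node_indices)


def particle_frequencies(mol: SpicesMolecule) -> dict[str, int]:
    """Occurrence count per particle name; counts sum to the node count."""
    return dict(Counter(n.name for n in mol.nodes))


def next_neighbors(mol: SpicesMolecule, depth: int) -> dict[int, list[set[int]]]:
    """Per-node neighbor shells up to ``depth`` bonds away.

    Shell ``k`` (1-based; list position ``k-1``) of node ``v`` contains the
    nodes at graph distance exactly ``k`` from ``v``; shell 1 is the bond
    adjacency.  Shells beyond a node's eccentricity are empty sets.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    adj = mol.adjacency()
    result: dict[int, list[set[int]]] = {}
    for v in range(len(mol.nodes)):
        shells: list[set[int]] = [set() for _ in range(depth)]
        dist = {v: 0}
        queue = deque([v])
        while queue:
            u = queue.popleft()
            if dist[u] == depth:
                continue
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    shells[dist[w] - 1].add(w)
                    queue.append(w)
        result[v] = shells
    return result


def connected_parts(mol: SpicesMolecule) -> list[SpicesMolecule]:
    """Split a multi-part molecule into its independent parts.

    Each part becomes a single-part molecule with nodes reindexed to
    ``0..k-1`` preserving relative notation order.
    """
    from .notation import ParticleNode  # local to avoid polluting module ns

    out: list[SpicesMolecule] = []
    for p in range(mol.parts):
        members = mol.part_node_indices(p)
        remap = {old: new for new, old in enumerate(members)}
        nodes = tuple(
            ParticleNode(index=remap[m], part_index=0,
                         name=mol.nodes[m].name,
                         backbone_label=mol.nodes[m].backbone_label,
                         tags=mol.nodes[m].tags)
            for m in members)
        bonds = frozenset(
            (remap[i], remap[j]) for i, j in mol.bonds
            if i in remap and j in remap)
        out.append(SpicesMolecule(nodes=nodes, bonds=bonds, parts=1,
                                  source_text=None))
    return out


def _require_single_part(part: SpicesMolecule) -> None:
    if part.parts != 1:
        raise StructureError(
            f"expected a single connected part, got {part.parts} parts")
    if not part.nodes:
        raise StructureError("empty molecule")


def _dfs_tree(adj: list[list[int]], root: int
              ) -> tuple[dict[int, Optional[int]], dict[int, int]]:
    """Iterative DFS visiting neighbors in ascending index order.

    Returns (parent, depth) maps over the reachable component; depth is the
    DFS-tree depth at first visit.
    """
    parent: dict[int, Optional[int]] = {root: None}
    depth = {root: 0}
    stack = [root]
    while stack:
        v = stack.pop()
        for w in sorted(adj[v], reverse=True):  # pop order = ascending
            if w not in depth:
                parent[w] = v
                depth[w] = depth[v] + 1
                stack.append(w)
    return parent, depth


def _farthest(depth: dict[int, int]) -> int:
    """Deepest node; ties broken toward the lowest notation index."""
    best = None
    best_depth = -1
    for v in sorted(depth):
        if depth[v] > best_depth:
            best, best_depth = v, depth[v]
    assert best is not None
    return best


def _tree_path(parent: dict[int, Optional[int]], leaf: int) -> list[int]:
    path = [leaf]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])  # type: ignore[arg-type]
    path.reverse()
    return path


def longest_chain(part: SpicesMolecule) -> ChainPath:
    """Double-sweep longest-chain search, untagged.

    A first DFS from the first notation particle finds the maximum-distant
    particle A; a second DFS from A finds the maximum-distant particle B;
    the realized A→B path of the second DFS tree is returned.  Exact on
    trees; on cyclic parts the result may be shorter than the true longest
    path (accepted).  Ties in "maximum-distant" go to the lowest notation
    index, so repeated calls are identical.
    """
    _require_single_part(part)
    adj = part.adjacency()
    _parent1, depth1 = _dfs_tree(adj, 0)
    if len(depth1) != len(part.nodes):
        raise StructureError("part is not connected")
    a = _farthest(depth1)
    parent2, depth2 = _dfs_tree(adj, a)
    b = _farthest(depth2)
    path = _tree_path(parent2, b)
    # untagged chains have two admissible orientations; fix the one whose
    # first particle has the lower notation index
    if path[0] > path[-1]:
        path.reverse()
    return ChainPath(tuple(path), oriented=False)


def _tagged_endpoints(part: SpicesMolecule) -> tuple[int, int]:
    starts = [n.index for n in part.nodes if "START" in n.tags]
    ends = [n.index for n in part.nodes if "END" in n.tags]
    if len(starts) != 1 or len(ends) != 1:
        raise TagError(
            f"oriented chain needs exactly one [START] and one [END] tag, "
            f"found {len(starts)} and {len(ends)}")
    return starts[0], ends[0]


def longest_chain_oriented(part: SpicesMolecule,
                           state_budget: int = DEFAULT_STATE_BUDGET
                           ) -> ChainPath:
    """Longest simple path from the [START] node to the [END] node.

    An exhaustive backtracking DFS over simple paths (neighbors visited in
    ascending index order; among equally long paths the first found wins).
    If more than ``state_budget`` node expansions are spent — possible only
    on densely cyclic parts — the search stops and returns the best path
    found so far, or failing that the plain DFS-tree path from START to
    END.  Acyclic molecules are always searched exactly.
    """
    _require_single_part(part)
    s, e = _tagged_endpoints(part)
    adj = part.adjacency()
    parent, depth = _dfs_tree(adj, s)
    if len(depth) != len(part.nodes):
        raise StructureError("part is not connected")
    if e not in depth:  # unreachable only if disconnected
        raise StructureError("END particle not reachable from START")

    best: Optional[list[int]] = None
    states = 0
    exhausted_budget = False
    path = [s]
    on_path = {s}
    iters = [iter(adj[s])]
    while iters and not exhausted_budget:
        advanced = False
        for w in iters[-1]:
            if w in on_path:
                continue
            states += 1
            if states > state_budget:
                exhausted_budget = True
                break
            if w == e:
                if best is None or len(path) + 1 > len(best):
                    best = path + [w]
                continue  # a simple path cannot extend past its endpoint
            path.append(w)
            on_path.add(w)
            iters.append(iter(adj[w]))
            advanced = True
            break
        if not advanced and not exhausted_budget:
            iters.pop()
            on_path.discard(path.pop())

    if best is None:
        best = _tree_path(parent, e)
    return ChainPath(tuple(best), oriented=True)
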