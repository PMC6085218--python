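"""Linear 3D tube construction for simulation start geometries.

Mesoscopic techniques such as Dissipative Particle Dynamics use soft pair
potentials, so particles may overlap or even coincide exactly.  That frees
the start geometry from steric realism: a molecule can be laid out as a
straight "tube" — its main particle chain lined up along a caller-supplied
start→end line at the requested bond length — with every side-chain
particle collapsed onto the position of its nearest main-chain particle.

Two rules govern the spacing along the line:

* overshoot — if the line is longer than the chain's accumulated bond
  lengths, the spacing stays at the bond length and the tube simply ends
  short of the end point (the start point is always hit exactly);
* squeeze — if the line is shorter, the spacing is reduced uniformly to
  ``|end - start| / (m - 1)`` so the chain exactly spans the line.

"Nearest main-chain particle" is measured in bond-count graph distance
(positions do not exist yet when the assignment is made); ties go to the
lower main-chain position index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque
from typing import Mapping, Optional, Sequence

import numpy as np

from .notation import SpicesMolecule, SpicesError, StructureError
from .topology import ChainPath, longest_chain, longest_chain_oriented

__all__ = [
    "GeometryError",
    "LineSpec",
    "TubeMapping",
    "BoxRecord",
    "BoxRecordTable",
    "map_molecule_to_line",
    "particle_positions_and_connections",
]


class GeometryError(SpicesError):
    """Invalid line/box geometry (zero-length line, over-long tube, ...)."""


def _as_point(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise GeometryError(f"expected a 3D point, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class LineSpec:
    """A start→end segment in box-length units plus the target bond length.

    The start point is where the first main-chain particle is anchored;
    the direction start→end orients the tube.
    """

    start: np.ndarray
    end: np.ndarray
    bond_length: float

    def __post_init__(self):
        object.__setattr__(self, "start", _as_point(self.start))
        object.__setattr__(self, "end", _as_point(self.end))
        if not np.all(np.isfinite(self.start)) or not np.all(np.isfinite(self.end)):
            raise GeometryError("line endpoints must be finite")
        if float(np.linalg.norm(self.end - self.start)) == 0.0:
            raise GeometryError("degenerate line: start equals end")
        if not self.bond_length > 0:
            raise GeometryError("bond_length must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class TubeMapping:
    """Every particle's 3D position after tube construction.

    ``positions[i]`` is node i's coordinate; main-chain nodes sit on the
    start→end line at uniform ``effective_bond_length`` spacing, each
    side-chain node is a bit-identical copy of its host main-chain node's
    position.  ``host[i]`` gives the main-chain node index node i was
    collapsed onto (a main-chain node hosts itself).
    """

    positions: np.ndarray            # (n_nodes, 3)
    main_chain: ChainPath
    effective_bond_length: float
    host: np.ndarray                 # (n_nodes,) int

    def chain_position_index(self) -> np.ndarray:
        """Per-node index of its host along the main chain (0-based)."""
        chain_pos = {v: k for k, v in enumerate(self.main_chain.node_indices)}
        return np.array([chain_pos[h] for h in self.host], dtype=int)


def _collapse_hosts(adj: list[list[int]], chain: Sequence[int],
                    n_nodes: int) -> np.ndarray:
    """Assign every node the nearest main-chain node by bond-count distance.

    Multi-source BFS seeded with the chain nodes in chain-position order:
    FIFO processing guarantees minimum distance, and seeding order makes
    ties resolve to the lower chain position index.
    """
    host = np.full(n_nodes, -1, dtype=int)
    queue: deque[int] = deque()
    for c in chain:
        host[c] = c
        queue.append(c)
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if host[w] < 0:
                host[w] = host[v]
                queue.append(w)
    if np.any(host < 0):
        raise StructureError("molecule is not connected")
    return host


def map_molecule_to_line(mol: SpicesMolecule, line: LineSpec) -> TubeMapping:
    """Lay a single-part molecule out as a linear 3D tube on ``line``.

    The main chain is the tag-oriented longest chain when the part carries
    a [START]/[END] pair, otherwise the untagged double-sweep chain.  With
    ``m`` main-chain particles, line length ``L`` and bond length ``b``,
    the realized spacing is ``b`` when ``(m-1)·b ≤ L`` (the tube may end
    short of the end point) and ``L/(m-1)`` otherwise (uniform squeeze).
    A single-particle molecule sits at the start point with effective
    bond length 0.
    """
    if mol.parts != 1:
        raise StructureError("tube mapping needs a single-part molecule")
    has_tags = (mol.tagged_node("START") is not None
                and mol.tagged_node("END") is not None)
    chain = (longest_chain_oriented(mol) if has_tags else longest_chain(mol))
    m = len(chain)
    if m == 1:
        positions = np.tile(line.start, (1, 1))
        host = np.zeros(1, dtype=int)
        return TubeMapping(positions=positions, main_chain=chain,
                           effective_bond_length=0.0, host=host)
    L = line.length
    needed = (m - 1) * line.bond_length
    spacing = line.bond_length if needed <= L else L / (m - 1)
    adj = mol.adjacency()
    host = _collapse_hosts(adj, chain.node_indices, len(mol.nodes))
    chain_pos = {v: k for k, v in enumerate(chain.node_indices)}
    t = np.array([chain_pos[h] for h in host], dtype=float)
    u = line.direction
    positions = line.start[None, :] + (t[:, None] * spacing) * u[None, :]
    # re-anchor exactly: floating arithmetic already gives start + 0*u, but
    # be explicit that the first chain particle is the start point verbatim
    positions[t == 0.0] = line.start
    return TubeMapping(positions=positions, main_chain=chain,
                       effective_bond_length=float(spacing), host=host)


# ---------------------------------------------------------------------------
# Simulation-kernel record table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxRecord:
    """One tabular record: particle name, position, signed bond offsets to
    every bonded partner record, and a force-assignment index."""

    name: str
    x: float
    y: float
    z: float
    bond_offsets: tuple[int, ...]
    force_index: int


@dataclass
class BoxRecordTable:
    """Ordered simulation-kernel records stored column-wise.

    Column storage (name list, (N,3) coordinate array, per-record offset
    tuples, integer force indices) keeps population-scale tables cheap;
    iteration yields :class:`BoxRecord` row views.  ``box_lengths``, when
    set, records the simulation-box extents for the ASCII header and the
    write-time clamping policy.
    """

    names: list[str]
    coords: np.ndarray                       # (N, 3) float
    bond_offsets: list[tuple[int, ...]]
    force_indices: np.ndarray                # (N,) int
    box_lengths: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.force_indices = np.asarray(self.force_indices, dtype=int).reshape(-1)
        n = len(self.names)
        if not (self.coords.shape[0] == len(self.bond_offsets)
                == self.force_indices.shape[0] == n):
            raise StructureError("record table columns have mismatched lengths")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> BoxRecord:
        x, y, z = self.coords[i]
        return BoxRecord(self.names[i], float(x), float(y), float(z),
                         self.bond_offsets[i], int(self.force_indices[i]))

    def check_offsets(self) -> None:
        """Verify offset closure: i+d in range and record i+d lists -d."""
        n = len(self)
        for i, offsets in enumerate(self.bond_offsets):
            for d in offsets:
                j = i + d
                if not 0 <= j < n:
                    raise StructureError(
                        f"record {i}: offset {d:+d} points outside the table")
                if -d not in self.bond_offsets[j]:
                    raise StructureError(
                        f"record {i}: offset {d:+d} not mirrored by record {j}")

    def total_bonds(self) -> int:
        return sum(len(o) for o in self.bond_offsets) // 2


def particle_positions_and_connections(
        mol: SpicesMolecule,
        mapping: TubeMapping,
        force_index: Optional[Mapping[int, int]] = None) -> BoxRecordTable:
    """Emit one record per particle in notation order.

    Bond offsets are the signed record-index differences to every bonded
    partner, sorted ascending; ``force_index`` maps node index → integer
    force-assignment index (absent nodes get 0).
    """
    n = len(mol.nodes)
    if mapping.positions.shape[0] != n:
        raise StructureError(
            f"mapping covers {mapping.positions.shape[0]} nodes, "
            f"molecule has {n}")
    force_index = force_index or {}
    adj = mol.adjacency()
    offsets = [tuple(sorted(j - i for j in adj[i])) for i in range(n)]
    forces = np.array([int(force_index.get(i, 0)) for i in range(n)], dtype=int)
    return BoxRecordTable(
        names=[node.name for node in mol.nodes],
        coords=mapping.positions.copy(),
        bond_offsets=offsets,
        force_indices=forces,
    )
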