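"""Built-in example molecules and a random-molecule generator.

The fixtures are self-contained SPICES strings that exercise every
notation feature without external data:

* :func:`fixture_dmpc` — a 16-particle DMPC phospholipid fragmentation
  (trimethylammonium-propyl head, phosphate-glycerol linker, two ester +
  hexa-ethylene tails) with [START]/[END] tags on the head and the end of
  one tail.
* :func:`fixture_cholesterol_like` — a fused-ring sterol analog whose 17
  particles all carry backbone labels '1'..'17', for testing labels and
  ring closures together.  The topology is a structural analog of a
  steroid ring system (three fused rings plus a short tail), not a
  literal cholesterol fragmentation.

:func:`random_molecule` produces seeded, always-valid random strings for
property tests: a random tree with tunable branching, optional extra
ring-closure bonds, and occasional backbone labels and tag pairs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .notation import ParticleNode, SpicesMolecule, serialize

__all__ = [
    "fixture_dmpc",
    "fixture_cholesterol_like",
    "random_molecule",
    "FIXTURES",
]

_DEFAULT_ALPHABET = ("Et", "Me", "MeAc", "PrOH", "AcNH", "W")


def fixture_dmpc() -> str:
    """SPICES string of a 16-particle DMPC phospholipid decomposition.

    Head particle TriMeNP carries [START]; the phosphate-glycerol particle
    DMPN holds a side branch of one ester (MeAc) plus six chained ethylene
    (Et) particles, while the main chain continues through the second
    ester and six more Et to the [END]-tagged terminal particle.  Tree
    topology: 16 particles, 15 bonds; the oriented main chain has 9
    particles.
    """
    return "TriMeNP[START]-DMPN(-MeAc-6Et)-MeAc-5Et-Et[END]"


def fixture_cholesterol_like() -> str:
    """A fused-ring sterol-analog string with backbone labels '1'..'17'.

    Three fused rings (two six-membered, one five-membered, sharing
    particles 6 and 11) plus a two-particle tail; every particle is
    labeled so label→force-index assignment can be exercised on a cyclic
    molecule.
    """
    return ("MeOH'1'[1]-Me'2'-Me'3'-Me'4'-Me'5'-Me'6'[1][2]"
            "-Me'7'-Me'8'-Me'9'-Me'10'-Me'11'[2][3]"
            "-Me'12'-Me'13'-Me'14'-Me'15'[3]-Et'16'-Et'17'")


FIXTURES = {
    "dmpc": fixture_dmpc,
    "cholesterol": fixture_cholesterol_like,
}


def random_molecule(n_particles: int,
                    branch_prob: float = 0.3,
                    ring_prob: float = 0.0,
                    alphabet: Sequence[str] = _DEFAULT_ALPHABET,
                    seed: int = 0,
                    label_prob: float = 0.1,
                    tag_prob: float = 0.3) -> str:
    """Seeded random single-part SPICES string with ``n_particles`` nodes.

    A random tree is grown node by node: each new node attaches to the
    previous one, or with probability ``branch_prob`` to a uniformly
    random earlier node.  Each node then closes an extra ring bond to a
    non-adjacent earlier node with probability ``ring_prob`` (so
    ``ring_prob=0`` guarantees a tree with ``n-1`` bonds).  Nodes draw
    names uniformly from ``alphabet``; ``label_prob`` adds per-node
    backbone labels and ``tag_prob`` a [START]/[END] pair on two distinct
    nodes.  The output always passes :func:`spices.notation.validate`.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if not (0 <= branch_prob <= 1 and 0 <= ring_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [str(rng.choice(alphabet)) for _ in range(n_particles)]
    bonds: set[tuple[int, int]] = set()
    adjacent: list[set[int]] = [set() for _ in range(n_particles)]

    def add_bond(a: int, b: int) -> None:
        bonds.add((min(a, b), max(a, b)))
        adjacent[a].add(b)
        adjacent[b].add(a)

    for i in range(1, n_particles):
        parent = int(rng.integers(0, i)) if rng.random() < branch_prob else i - 1
        add_bond(parent, i)
    for i in range(2, n_particles):
        if rng.random() < ring_prob:
            candidates = [j for j in range(i - 1) if j not in adjacent[i]]
            if candidates:
                add_bond(int(rng.choice(candidates)), i)

    labels: list[Optional[str]] = [
        str(int(rng.integers(1, 100))) if rng.random() < label_prob else None
        for _ in range(n_particles)]
    tags: list[frozenset[str]] = [frozenset()] * n_particles
    if n_particles >= 2 and rng.random() < tag_prob:
        a, b = rng.choice(n_particles, size=2, replace=False)
        tags[int(a)] = frozenset({"START"})
        tags[int(b)] = frozenset({"END"})

    mol = SpicesMolecule(
        nodes=tuple(ParticleNode(i, 0, names[i], labels[i], tags[i])
                    for i in range(n_particles)),
        bonds=frozenset(bonds),
        parts=1,
    )
    return serialize(mol)
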