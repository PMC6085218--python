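# Methods

## Model

A SPICES molecule is an undirected vertex-labeled graph: vertices are
coarse-grained "molecular fragment" particles (opaque names — no charges,
valences or stereochemistry; chemically distinct states are distinct
particles), edges are harmonic-spring bonds.  A string may contain
several independent parts (e.g. protein quaternary structure); each part
must be internally connected and bonds never span parts.  Per-particle
*backbone labels* (`'1'`…`'17'` style) are identity hooks for
label → force-index assignment at projection time; they carry no force
semantics themselves.  At most one `[START]` and one `[END]` tag per part
fix the main-chain orientation for spatial mapping.

## Grammar decisions

The notation features (branches, ring closures, labels, tags, parts,
repeat counts) are fixed semantics; the surface syntax is this package's
normative dialect (see README).  Choices made where the surface form was
open:

* explicit `-` between bonded particles, since multi-character particle
  names would otherwise be ambiguous;
* `.` as the part separator, following SMILES;
* `[k]` ring closures with a positive integer appearing exactly twice per
  part; after parsing a ring bond is indistinguishable from a chain bond;
* `nX` repeat prefixes expand to `n` linearly chained copies; a repeated
  particle cannot carry a label or tag (labels are per-occurrence
  identities), while a following branch or ring closure attaches to the
  last copy.  `n` is capped at 10 000 so a few characters cannot expand
  into an arbitrarily large graph;
* whitespace and non-ASCII bytes are errors anywhere, keeping reported
  character offsets unambiguous.

The validator recovers after every error and reports all problems with
0-based offsets; the parser raises at the first.  The serializer emits a
spanning-tree traversal (ascending-index children, non-tree edges as ring
closures) and guarantees only an attribute-preserving isomorphic
re-parse — the notation is not canonically unique and no canonical form
is attempted.

## Chain search

The main chain is found by a double DFS: from the first notation particle
to the maximum-distant particle A (distance = DFS-tree depth, neighbors
visited in ascending index order), then from A to the maximum-distant B,
returning the realized A→B tree path.  On acyclic parts DFS-tree depth
equals graph distance, so this is a true longest path; on cyclic parts
the result may be sub-maximal, which is accepted — start geometries only
need a sufficiently long chain.  Two deterministic tie-breaks: the
maximum-distance particle with the lowest notation index wins, and an
untagged chain (which has two admissible orientations) is returned with
its lower-indexed endpoint first.

With a `[START]`/`[END]` pair the chain is instead the longest simple
path between the tagged particles, found by exhaustive backtracking DFS
(first-found wins among equal lengths).  Simple-path enumeration is
exponential on dense cycle systems, so the search is capped at a
state budget of 10⁴ node expansions (tunable per call); beyond it the
best path found so far is returned, or failing that the DFS-tree path
from START to END.  Trees and the small cyclic molecules the notation is
aimed at are always searched exactly.

## Tube construction

Given a start→end line and bond length `b` (box-length units), the `m`
main-chain particles are placed collinearly from the start point at
uniform spacing `min(b, L/(m−1))`: the tube overshoots short of the end
point when the line is long, and squeezes uniformly when it is short, so
calling code only has to supply valid lines, never pre-check lengths.
A single-particle molecule sits at the start with effective bond length
0; a zero-length line is rejected (no direction).  Every non-chain
particle is collapsed onto the main-chain particle at minimum bond-count
distance — the only metric defined before positions exist — with ties to
the lower chain-position index, implemented as one multi-source BFS
seeded in chain order.  Collapsed positions are bit-identical copies of
the host position (coincidence is physical under soft DPD potentials),
and nested side branches collapse directly onto their nearest main-chain
particle.

## Box populations and the ASCII dialect

`random_lines` draws uniform start points and uniform-on-sphere
directions (normalized Gaussian triples), resampling the orientation up
to 1000 times until the end point is inside the box.  `bilayer_lines`
places `n/2` lines per leaflet parallel to the normal axis, running from
`midplane ± tube_length` toward the midplane, so `[START]`-tagged head
groups face outward in both leaflets; lateral positions are uniform.
Randomness uses one root seed with per-line streams derived by counter
offset (`default_rng([seed, line_index])`), so output is byte-reproducible
and independent of chunking.

`project_population` computes the molecule's chain, collapse assignment
and bond offsets once and reuses them for every line (positions are one
vectorized broadcast), which keeps 50 000 × 16-particle projections at
sub-second cost.  Records are concatenated per molecule in line order;
bond offsets are signed record-index differences, sorted ascending, and
stay intra-molecular.  Force indices come from a strict backbone-label
map (a labeled particle missing from a non-empty map is an error unless
permissive mode is chosen; unlabeled particles get 0).

The tabular ASCII dialect is this package's normative format: `#` header
lines with box extents and record count, then tab-separated
`name x y z offsets force_index` with 6-decimal fixed coordinates and
comma-separated signed offsets.  Coordinates are clamped inclusively
into `[0, extent]` at write time when the box is known; reading a written
file and writing again is a byte fixpoint because coordinates round-trip
at the printed precision.

## Synthetic molecules

`random_molecule` grows a random tree (each new particle attaches to the
previous one, or with probability `branch_prob` to a uniform earlier
one), adds extra ring bonds with probability `ring_prob` per particle,
and sprinkles backbone labels (10 %) and a `[START]`/`[END]` pair (30 %
of molecules).  It emulates the topological variety of fragment
decompositions — branching, small cycle systems, labels, tags — but not
chemical realism: names are arbitrary, ring sizes are unconstrained and
no fragmentation rules apply.  Passing round-trip and chain tests on it
therefore demonstrates graph-level correctness, not chemical validity of
any particular particle set.  Test problem sizes (≤ 16 particles per
random molecule, 200 trees for chain exactness, 500 round trips, 10⁴
random lines for uniformity checks, one 50 000-molecule projection) were
chosen as the package's own test-budget choice: small enough to run in
seconds, large enough to exercise every code path.

## Known limitations

* The linear tube is a start geometry, not a conformation; for large
  cross-linked polymers a topology-only tube is questionable in
  principle, and structure-aware converters (e.g. PDB-derived input) are
  out of scope.
* Cyclic molecules may map to different tubes from different but
  equivalent notations (the chain search is notation-order dependent);
  for small molecules the resulting start geometries are equivalent in
  practice.
* No DPD force-field parametrization, concentration or length-scale
  calculation, and no periodic-boundary wrapping: boxes clamp, callers
  own the compartment logic.
* Interactive graph viewing is delegated to external tools via DOT and
  GraphML export.
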