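# spices

A Python toolkit for **SPICES** (Simplified Particle Input ConnEction
Specification), a particle-based molecular line notation for mesoscopic
simulation techniques such as Dissipative Particle Dynamics (DPD).

In DPD and related methods the interacting entities are not atoms but
"molecular fragment" particles of roughly 100 Da; larger molecules are
graphs of such particles bonded by harmonic springs.  Writing the tabular
input files these simulation kernels consume — one line per particle with
coordinates, bond offsets and force indices — by hand is tedious and
error-prone.  SPICES is a SMILES-derived line notation that makes the
topology a short, human-readable string, and this package provides the
machinery around it:

* **notation** — tokenizer, parser with positional error reporting,
  validator, and a serializer that writes graphs back to notation;
* **topology** — particle frequencies, neighbor shells, connected parts,
  and the double-DFS longest-chain search;
* **geometry** — conversion of a molecule into a linear 3D "tube":
  main-chain particles lined up along a start→end line, side-chain
  particles collapsed onto their nearest main-chain particle (soft DPD
  potentials permit exactly coincident particles);
* **boxsetup** — random or bilayer-oriented placement of molecule
  populations in a simulation box and tabular-ASCII input-file I/O;
* **export / cli** — DOT/GraphML particle-graph export and a `spices`
  command-line front end.

## The notation

Particles are letter-initial alphanumeric tokens joined by `-` bonds, with
SMILES-style branches and ring closures:

```
spices  := part ("." part)*          # independent parts
part    := group ("-" group)*
group   := unit branch*
unit    := COUNT NAME                # nX = n copies of X chained linearly
         | NAME label? tag? ring*
branch  := "(" "-"? part ")"         # bonds to the preceding particle
ring    := "[" INT "]"               # label appears exactly twice per part
label   := "'" TEXT "'"              # backbone label, e.g. Me'12'
tag     := "[START]" | "[END]"       # main-chain orientation markers
```

Charges and stereochemistry are deliberately absent — differently charged
or chiral fragments are distinct particles.  Backbone labels carry no
force themselves; they are indirection points for a label → force-index
map applied at projection time.

The 16-particle DMPC phospholipid fragmentation shipped as a fixture:

```
TriMeNP[START]-DMPN(-MeAc-6Et)-MeAc-5Et-Et[END]
```

## The tube algorithm

For a start geometry, a molecule's main chain is found with a double
depth-first search: DFS from the first particle to the maximum-distant
particle A, then DFS from A to the maximum-distant particle B; the
realized A→B path is the chain (exact on acyclic molecules; on cyclic
ones a possibly shorter chain is accepted).  With a `[START]`/`[END]` tag
pair the longest simple path between the tagged particles is used
instead, so the orientation is fixed.

With `m` chain particles, bond length `b` and a start→end line of length
`L`, the realized spacing is `b` when `(m−1)·b ≤ L` — the tube may end
short of the end point — and `L/(m−1)` otherwise (a uniform *squeeze*).
Every side-chain particle takes the exact position of its nearest
main-chain particle by bond-count distance.  The first chain particle
always sits exactly on the start point.

## Worked example

```
$ spices stats "$(spices fixtures dmpc)"
source  <arg>
parts   1
particles       16
particle        DMPN    1
particle        Et      12
particle        MeAc    2
particle        TriMeNP 1
chain   0       9       oriented
```

The DMPC fixture parses to 16 particles; its oriented main chain (head
TriMeNP → phosphate DMPN → ester MeAc → six Et) has 9 particles, so the
7 side-branch particles collapse onto the chain — all of them onto DMPN,
which therefore shares its position with 8 particles in total.

Projecting four molecules as a minimal bilayer:

```
$ spices project --string "$(spices fixtures dmpc)" --box 20,20,20 \
      --n 4 --mode bilayer --tube-length 8 --seed 1 --out bilayer.tsv
$ head -4 bilayer.tsv
# box   20.000000       20.000000       20.000000
# records       64
TriMeNP 10.236432       19.009274       18.000000       +1      0
DMPN    10.236432       19.009274       17.000000       -1,+1,+8        0
```

Each data line is `name  x  y  z  bond-offsets  force-index`: the head
particle at the outer leaflet face bonds the next record (`+1`); DMPN
bonds back to the head (`-1`), forward along the main chain (`+1`) and to
the first particle of its side branch eight records down (`+8`).  In
Python the same pipeline is:

```python
from spices import (SimulationBox, fixture_dmpc, parse,
                    bilayer_lines, project_population, write_ascii_table)

mol = parse(fixture_dmpc())
box = SimulationBox((20, 20, 20))
lines = bilayer_lines(box, 200, "z", midplane=10, tube_length=8, seed=1)
table = project_population(mol, lines, box=box)   # 3200 records
write_ascii_table(table, "bilayer.tsv")
```

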