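"""Simulation-box start geometries and the tabular ASCII kernel format.

A DPD start configuration is a population of molecules, each laid out as a
linear 3D tube (see :mod:`spices.geometry`) on its own start→end line
inside the box.  This module generates those lines — uniformly random
placement/orientation, or bilayer orientation with the tag-oriented head
groups facing away from the midplane — projects a molecule onto every
line, assigns per-particle force indices from backbone labels, and
reads/writes the resulting record table as tab-separated ASCII.

ASCII dialect (normative for this package): ``#``-prefixed header lines
carry the box extents and record count; every data line holds

    name <TAB> x <TAB> y <TAB> z <TAB> offsets <TAB> force_index

with coordinates in fixed 6-decimal notation and ``offsets`` a
comma-separated list of signed record-index differences to the bonded
partners (empty for an unbonded particle).  Coordinates are clamped
inclusively into ``[0, extent]`` per axis on write when the box is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .notation import SpicesMolecule, SpicesError, StructureError
from .geometry import (BoxRecordTable, GeometryError, LineSpec, TubeMapping,
                       map_molecule_to_line,
                       particle_positions_and_connections)

__all__ = [
    "SimulationBox",
    "TableFormatError",
    "random_lines",
    "bilayer_lines",
    "project_population",
    "write_ascii_table",
    "read_ascii_table",
]

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}

#: Orientation resampling attempts before giving up on a random line.
_MAX_ATTEMPTS = 1000


class TableFormatError(SpicesError):
    """Malformed tabular ASCII input; carries line number and field."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class SimulationBox:
    """Axis-aligned box with the origin at one corner."""

    lengths: tuple[float, float, float]

    def __post_init__(self):
        lengths = tuple(float(v) for v in self.lengths)
        if len(lengths) != 3 or any(not v > 0 for v in lengths):
            raise GeometryError("box needs 3 positive extents")
        object.__setattr__(self, "lengths", lengths)

    @property
    def extents(self) -> np.ndarray:
        return np.array(self.lengths, dtype=float)

    def contains(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= 0.0) and np.all(p <= self.extents))


def _line_rng(seed: int, index: int) -> np.random.Generator:
    # one root seed, per-line stream by counter offset
    return np.random.default_rng([int(seed), int(index)])


def random_lines(box: SimulationBox, n: int, tube_length: float,
                 seed: int, bond_length: float = 1.0) -> list[LineSpec]:
    """``n`` tube axes with uniform start points and orientations.

    Directions are drawn uniformly on the sphere (normalized Gaussian
    triples) and resampled until the end point lies inside the box (at
    most 1000 attempts per line).  Deterministic under ``seed``: each line
    draws from its own counter-derived stream.
    """
    if n < 1:
        raise GeometryError("need at least one line")
    if not 0 < tube_length <= min(box.lengths):
        raise GeometryError(
            f"tube length {tube_length} does not fit the box {box.lengths}")
    lines: list[LineSpec] = []
    for i in range(n):
        rng = _line_rng(seed, i)
        start = rng.uniform(0.0, box.extents)
        for _attempt in range(_MAX_ATTEMPTS):
            d = rng.normal(size=3)
            norm = np.linalg.norm(d)
            if norm == 0.0:
                continue
            end = start + (tube_length / norm) * d
            if box.contains(end):
                lines.append(LineSpec(start, end, bond_length))
                break
        else:
            raise GeometryError(
                f"could not orient line {i} inside the box "
                f"after {_MAX_ATTEMPTS} attempts")
    return lines


def bilayer_lines(box: SimulationBox, n: int,
                  normal_axis: Union[int, str], midplane: float,
                  tube_length: float, seed: int,
                  bond_length: float = 1.0) -> list[LineSpec]:
    """``n`` tube axes in bilayer orientation around ``midplane``.

    Every line is parallel to ``normal_axis``; the first ``n/2`` lines form
    leaflet 1 (running from ``midplane + tube_length`` down to the
    midplane), the rest mirror them from below, so the tag-oriented
    [START] particles — the head groups — face away from the midplane in
    both leaflets.  Lateral positions are uniform under ``seed``.
    """
    axis = _AXES.get(normal_axis if isinstance(normal_axis, int)
                     else str(normal_axis).lower())
    if axis is None:
        raise GeometryError(f"invalid normal axis {normal_axis!r}")
    if n < 2 or n % 2:
        raise GeometryError("bilayer population size must be even and >= 2")
    if not 0 < tube_length <= box.lengths[axis] / 2:
        raise GeometryError(
            f"tube length {tube_length} exceeds half the box extent "
            f"along axis {axis}")
    if midplane - tube_length < 0 or midplane + tube_length > box.lengths[axis]:
        raise GeometryError(
            f"bilayer around midplane {midplane} with tube length "
            f"{tube_length} leaves the box")
    lateral = [a for a in range(3) if a != axis]
    lines: list[LineSpec] = []
    for i in range(n):
        rng = _line_rng(seed, i)
        start = np.zeros(3)
        for a in lateral:
            start[a] = rng.uniform(0.0, box.lengths[a])
        end = start.copy()
        if i < n // 2:     # leaflet 1: above the midplane, head up
            start[axis] = midplane + tube_length
        else:              # leaflet 2: mirrored below, head down
            start[axis] = midplane - tube_length
        end[axis] = midplane
        lines.append(LineSpec(start, end, bond_length))
    return lines


def _force_indices_from_labels(mol: SpicesMolecule,
                               force_map: Optional[Mapping[str, int]],
                               strict: bool) -> dict[int, int]:
    out: dict[int, int] = {}
    if not force_map:
        return out
    for node in mol.nodes:
        lab = node.backbone_label
        if lab is None:
            continue
        if lab in force_map:
            out[node.index] = int(force_map[lab])
        elif strict:
            raise StructureError(
                f"backbone label '{lab}' (particle {node.index}) has no "
                "entry in the force map")
    return out


def project_population(mol: SpicesMolecule, lines: Sequence[LineSpec],
                       force_map: Optional[Mapping[str, int]] = None,
                       strict: bool = True,
                       box: Optional[SimulationBox] = None) -> BoxRecordTable:
    """Project one molecule onto every line and concatenate the records.

    The output holds ``len(lines) × len(mol)`` records in line order; bond
    offsets stay intra-molecular (each molecule is an independent bonded
    block), so the per-block offsets equal the single-molecule ones.
    ``force_map`` maps backbone labels to force indices; with ``strict``
    (the default) a labeled particle missing from a non-empty map is an
    error, otherwise it falls back to 0.

    The molecule's topology, collapse assignment and bond offsets are
    computed once and reused, so population-scale projections reduce to a
    vectorized position computation per line.
    """
    if mol.parts != 1:
        raise StructureError("population projection needs a single-part molecule")
    if not lines:
        raise GeometryError("need at least one line")
    n_nodes = len(mol.nodes)
    forces = _force_indices_from_labels(mol, force_map, strict)

    mapping0 = map_molecule_to_line(mol, lines[0])
    template = particle_positions_and_connections(mol, mapping0, forces)
    t = mapping0.chain_position_index().astype(float)     # line-independent
    m = len(mapping0.main_chain)

    starts = np.stack([ln.start for ln in lines])          # (k, 3)
    if m == 1:
        coords = np.repeat(starts, n_nodes, axis=0)
    else:
        dirs = np.stack([ln.direction for ln in lines])
        lengths = np.array([ln.length for ln in lines])
        bonds = np.array([ln.bond_length for ln in lines])
        spacing = np.where((m - 1) * bonds <= lengths, bonds, lengths / (m - 1))
        # position(node, line) = start + t[node] * spacing[line] * dir[line]
        coords = (starts[:, None, :]
                  + (t[None, :, None] * spacing[:, None, None])
                  * dirs[:, None, :])
        coords[:, t == 0.0, :] = starts[:, None, :]        # exact anchoring
        coords = coords.reshape(-1, 3)

    k = len(lines)
    return BoxRecordTable(
        names=template.names * k,
        coords=coords,
        bond_offsets=template.bond_offsets * k,
        force_indices=np.tile(template.force_indices, k),
        box_lengths=box.lengths if box is not None else None,
    )


# ---------------------------------------------------------------------------
# Tabular ASCII I/O
# ---------------------------------------------------------------------------

def _open(target, mode: str):
    if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
        return open(target, mode, encoding="ascii"), True
    return target, False


def write_ascii_table(table: BoxRecordTable, destination) -> None:
    """Write a record table in the tabular ASCII dialect.

    ``destination`` is a path or an open text file.  When the table knows
    its box, extents go into the header and coordinates are clamped
    inclusively into ``[0, extent]``.
    """
    fh, close = _open(destination, "w")
    try:
        coords = table.coords
        if table.box_lengths is not None:
            ext = np.array(table.box_lengths)
            coords = np.clip(coords, 0.0, ext)
            fh.write("# box\t%.6f\t%.6f\t%.6f\n" % tuple(table.box_lengths))
        fh.write(f"# records\t{len(table)}\n")
        write = fh.write
        names = table.names
        offsets = table.bond_offsets
        forces = table.force_indices
        for i in range(len(table)):
            x, y, z = coords[i]
            off = ",".join("%+d" % d for d in offsets[i])
            write("%s\t%.6f\t%.6f\t%.6f\t%s\t%d\n"
                  % (names[i], x, y, z, off, forces[i]))
    finally:
        if close:
            fh.close()


def read_ascii_table(source) -> BoxRecordTable:
    """Read a tabular ASCII file back into a :class:`BoxRecordTable`.

    Raises :class:`TableFormatError` with the 1-based line number on any
    malformed line; ``write(read(write(t)))`` is byte-identical to
    ``write(t)`` since coordinates round-trip at the printed precision.
    """
    fh, close = _open(source, "r")
    try:
        names: list[str] = []
        coords: list[tuple[float, float, float]] = []
        bond_offsets: list[tuple[int, ...]] = []
        forces: list[int] = []
        box_lengths: Optional[tuple[float, float, float]] = None
        declared: Optional[int] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line[1:].strip().split("\t")
                if fields and fields[0] == "box":
                    if len(fields) != 4:
                        raise TableFormatError(lineno, "box header needs 3 extents")
                    try:
                        box_lengths = (float(fields[1]), float(fields[2]),
                                       float(fields[3]))
                    except ValueError:
                        raise TableFormatError(lineno, "invalid box extent")
                elif fields and fields[0] == "records":
                    try:
                        declared = int(fields[1])
                    except (IndexError, ValueError):
                        raise TableFormatError(lineno, "invalid record count")
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise TableFormatError(
                    lineno, f"expected 6 tab-separated fields, got {len(fields)}")
            name, xs, ys, zs, offs, fs = fields
            if not name:
                raise TableFormatError(lineno, "empty particle name (field 1)")
            try:
                xyz = (float(xs), float(ys), float(zs))
            except ValueError:
                raise TableFormatError(lineno, "invalid coordinate (fields 2-4)")
            try:
                off = tuple(int(tok) for tok in offs.split(",")) if offs else ()
            except ValueError:
                raise TableFormatError(lineno, "invalid bond offset (field 5)")
            try:
                force = int(fs)
            except ValueError:
                raise TableFormatError(lineno, "invalid force index (field 6)")
            names.append(name)
            coords.append(xyz)
            bond_offsets.append(off)
            forces.append(force)
        if declared is not None and declared != len(names):
            raise TableFormatError(
                0, f"header declares {declared} records, file has {len(names)}")
        return BoxRecordTable(
            names=names,
            coords=np.array(coords, dtype=float).reshape(-1, 3),
            bond_offsets=bond_offsets,
            force_indices=np.array(forces, dtype=int),
            box_lengths=box_lengths,
        )
    finally:
        if close:
            fh.close()
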