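"""Static particle-graph export for visual inspection.

Line notations are error-prone for branched and cyclic molecules; a graph
picture of the parsed topology makes mistakes obvious.  This module emits
the particle graph as DOT or GraphML text consumable by standard graph
viewers (Graphviz, Gephi, yEd, ...).  Vertices appear in notation order
and edges in sorted order, so output is deterministic.
"""

from __future__ import annotations

from xml.sax.saxutils import escape

from .notation import ParticleNode, SpicesMolecule, check_molecule

__all__ = ["export_graph"]


def _display_name(node: ParticleNode) -> str:
    out = node.name
    if node.backbone_label is not None:
        out += f"'{node.backbone_label}'"
    for tag in node.tags:
        out += f" [{tag}]"
    return out


def _dot(mol: SpicesMolecule) -> str:
    lines = ["graph spices {"]
    for node in mol.nodes:
        label = _display_name(node).replace("\\", "\\\\").replace('"', '\\"')
        lines.append(f'  n{node.index} [label="{label}"];')
    for i, j in sorted(mol.bonds):
        lines.append(f"  n{i} -- n{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _graphml(mol: SpicesMolecule) -> str:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="label" for="node" attr.name="label" attr.type="string"/>',
        '  <graph id="spices" edgedefault="undirected">',
    ]
    for node in mol.nodes:
        lines.append(f'    <node id="n{node.index}">'
                     f'<data key="label">{escape(_display_name(node))}</data>'
                     '</node>')
    for i, j in sorted(mol.bonds):
        lines.append(f'    <edge source="n{i}" target="n{j}"/>')
    lines += ["  </graph>", "</graphml>"]
    return "\n".join(lines) + "\n"


def export_graph(mol: SpicesMolecule, format: str = "dot") -> str:
    """Render the particle graph as a ``dot`` or ``graphml`` document.

    One vertex per particle (label = name, with the backbone label quoted
    and START/END flagged) and one edge per bond.
    """
    check_molecule(mol)
    if format == "dot":
        return _dot(mol)
    if format == "graphml":
        return _graphml(mol)
    raise ValueError(f"unknown export format {format!r} "
                     "(expected 'dot' or 'graphml')")
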