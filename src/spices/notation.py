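"""SPICES line notation: grammar, tokenizer, parser, validator, serializer.

SPICES (Simplified Particle Input ConnEction Specification) is a line
notation for particle-decomposed ("coarse-grained") molecules, patterned
after SMILES but with opaque multi-character particle tokens instead of
atoms.  A string describes one or more independent molecular parts as a
graph of named particles connected by bonds, with branches, ring closures,
per-particle backbone labels (used downstream to attach specific
inter-particle forces) and optional ``[START]``/``[END]`` tags that fix the
spatial orientation of the main chain.  Electric charges and stereo
descriptors are deliberately absent: differently charged or chiral
fragments are distinct particles.

Normative grammar of this implementation::

    spices  := part ("." part)*
    part    := group ("-" group)*
    group   := unit branch*
    unit    := COUNT NAME               # COUNT copies of NAME chained linearly
             | NAME label? tag? ring*
    branch  := "(" "-"? part ")"        # contents bond to the preceding particle
    ring    := "[" INT "]"              # positive label, exactly twice per part
    label   := "'" TEXT "'"             # non-empty, no quote characters
    tag     := "[START]" | "[END]"
    NAME    := [A-Za-z][A-Za-z0-9]*
    COUNT   := positive integer (capped at MAX_REPEAT)

Whitespace and non-ASCII characters are forbidden anywhere.  Ring-closure
bonds are ordinary bonds after parsing.  A repeated particle (``6Et``) may
not carry a backbone label or tag — labels are per-occurrence identities —
but a branch or ring closure after it attaches to the last copy.

:func:`validate` never raises; it scans past errors and reports every
problem it finds with a character offset.  :func:`parse` raises on the
first problem.  :func:`serialize` writes a parsed molecule back to a valid
string; since the notation is not canonically unique the output is only
guaranteed to re-parse to an isomorphic graph, not to reproduce the input
text.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "MAX_REPEAT",
    "ParticleNode",
    "SpicesMolecule",
    "ParseError",
    "ParseReport",
    "SpicesError",
    "SpicesSyntaxError",
    "UnknownParticleError",
    "StructureError",
    "TagError",
    "Token",
    "TokenKind",
    "tokenize",
    "parse",
    "validate",
    "serialize",
    "check_molecule",
    "iter_spices_file",
    "read_particle_catalog",
]

#: Upper bound on the ``nX`` repeat-prefix count.  Keeps a handful of
#: characters from expanding into an arbitrarily large particle graph.
MAX_REPEAT = 10_000

_NAME_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*\Z")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SpicesError(Exception):
    """Base class for all errors raised by this package."""


class SpicesSyntaxError(SpicesError):
    """Raised by :func:`parse` on invalid notation; carries the report."""

    def __init__(self, report: "ParseReport"):
        self.report = report
        first = report.errors[0] if report.errors else None
        msg = f"at offset {first.position}: {first.message}" if first else "invalid"
        super().__init__(msg)


class UnknownParticleError(SpicesError):
    """A particle name is absent from the supplied catalog."""

    def __init__(self, name: str, position: int):
        self.name = name
        self.position = position
        super().__init__(f"unknown particle '{name}' at offset {position}")


class StructureError(SpicesError):
    """A molecule violates a structural invariant."""


class TagError(StructureError):
    """Missing or duplicated [START]/[END] tags for an oriented operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleNode:
    """One particle occurrence within a SPICES string.

    ``index`` is the 0-based notation-order ordinal over the whole string,
    ``part_index`` the ordinal of the independent part the node belongs to.
    ``tags`` is a subset of ``{"START", "END"}`` with at most one member.
    """

    index: int
    part_index: int
    name: str
    backbone_label: Optional[str] = None
    tags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SpicesMolecule:
    """A parsed multi-part particle graph in notation order.

    ``bonds`` holds unordered index pairs stored as sorted tuples.  Node
    indices are consecutive ``0..N-1``; no bond spans two parts and every
    part is internally connected.
    """

    nodes: tuple[ParticleNode, ...]
    bonds: frozenset[tuple[int, int]]
    parts: int
    source_text: Optional[str] = None

    def __len__(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> list[list[int]]:
        """Sorted neighbor lists, indexed by node index."""
        adj: list[list[int]] = [[] for _ in self.nodes]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        for lst in adj:
            lst.sort()
        return adj

    def part_node_indices(self, part_index: int) -> list[int]:
        return [n.index for n in self.nodes if n.part_index == part_index]

    def tagged_node(self, tag: str, part_index: int = 0) -> Optional[int]:
        """Index of the node carrying ``tag`` in the given part, or None."""
        for n in self.nodes:
            if n.part_index == part_index and tag in n.tags:
                return n.index
        return None


@dataclass(frozen=True)
class ParseError:
    position: int
    length: int
    message: str


@dataclass(frozen=True)
class ParseReport:
    """Validity flag plus positional diagnostics; valid ⇔ no errors."""

    valid: bool
    errors: tuple[ParseError, ...] = ()

    def __bool__(self) -> bool:
        return self.valid


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

class TokenKind(enum.Enum):
    NAME = "name"
    COUNT = "count"
    BOND = "bond"
    OPEN = "open"
    CLOSE = "close"
    DOT = "dot"
    RING = "ring"
    LABEL = "label"
    TAG = "tag"
    ERROR = "error"


@dataclass(frozen=True)
class Token:
    kind: TokenKind
    value: object
    pos: int
    length: int


_SINGLE = {"-": TokenKind.BOND, "(": TokenKind.OPEN,
           ")": TokenKind.CLOSE, ".": TokenKind.DOT}


def tokenize(text: str) -> list[Token]:
    """Lex a SPICES string; never raises, bad input yields ERROR tokens."""
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if not ch.isascii():
            tokens.append(Token(TokenKind.ERROR, "non-ASCII character", i, 1))
            i += 1
        elif ch.isspace():
            tokens.append(Token(TokenKind.ERROR, "whitespace is not allowed", i, 1))
            i += 1
        elif ch.isalpha():
            j = i + 1
            while j < n and text[j].isascii() and text[j].isalnum():
                j += 1
            tokens.append(Token(TokenKind.NAME, text[i:j], i, j - i))
            i = j
        elif ch.isdigit():
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            tokens.append(Token(TokenKind.COUNT, int(text[i:j]), i, j - i))
            i = j
        elif ch in _SINGLE:
            tokens.append(Token(_SINGLE[ch], ch, i, 1))
            i += 1
        elif ch == "'":
            j = text.find("'", i + 1)
            if j < 0:
                tokens.append(Token(TokenKind.ERROR,
                                    "unterminated backbone label", i, n - i))
                i = n
            elif j == i + 1:
                tokens.append(Token(TokenKind.ERROR, "empty backbone label", i, 2))
                i = j + 1
            else:
                body = text[i + 1:j]
                if body.isascii() and body.isprintable():
                    tokens.append(Token(TokenKind.LABEL, body, i, j - i + 1))
                else:
                    tokens.append(Token(TokenKind.ERROR,
                                        "invalid backbone label text", i, j - i + 1))
                i = j + 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j < 0:
                tokens.append(Token(TokenKind.ERROR, "unterminated '['", i, n - i))
                i = n
            else:
                body = text[i + 1:j]
                if body in ("START", "END"):
                    tokens.append(Token(TokenKind.TAG, body, i, j - i + 1))
                elif body.isdigit() and int(body) > 0:
                    tokens.append(Token(TokenKind.RING, int(body), i, j - i + 1))
                else:
                    tokens.append(Token(
                        TokenKind.ERROR,
                        f"invalid bracket content '{body}' "
                        "(expected a positive ring label, START or END)",
                        i, j - i + 1))
                i = j + 1
        else:
            tokens.append(Token(TokenKind.ERROR,
                                f"unexpected character '{ch}'", i, 1))
            i += 1
    return tokens


# ---------------------------------------------------------------------------
# Parser / validator
# ---------------------------------------------------------------------------

@dataclass
class _NodeDraft:
    index: int
    part_index: int
    name: str
    backbone_label: Optional[str] = None
    tags: set[str] = field(default_factory=set)


@dataclass
class _BranchCtx:
    outer_last: Optional[int]
    open_pos: int
    had_particle: bool = False


def _scan(text: str) -> tuple[list[_NodeDraft], set[tuple[int, int]], int,
                              list[ParseError]]:
    """Single error-recovering pass shared by :func:`parse` and
    :func:`validate`.  Returns (node drafts, bonds, part count, errors)."""
    tokens = tokenize(text)
    errors: list[ParseError] = []
    nodes: list[_NodeDraft] = []
    bonds: set[tuple[int, int]] = set()

    def err(pos: int, length: int, message: str) -> None:
        errors.append(ParseError(pos, length, message))

    def add_bond(a: int, b: int, pos: int, length: int) -> None:
        if a == b:
            err(pos, length, "bond connects a particle to itself")
            return
        key = (a, b) if a < b else (b, a)
        if key in bonds:
            err(pos, length, "duplicate bond")
        else:
            bonds.add(key)

    # per-part state
    part_index = 0
    part_start = 0
    part_has_node = False
    part_tags: dict[str, int] = {}
    last: Optional[int] = None
    expect_particle = True
    at_branch_start = False
    pending_bond: Optional[Token] = None
    branch_stack: list[_BranchCtx] = []
    ring_open: dict[int, tuple[int, Token]] = {}
    label_target: Optional[int] = None
    tag_target: Optional[int] = None
    ring_target: Optional[int] = None

    def new_node(name: str) -> int:
        nonlocal part_has_node
        idx = len(nodes)
        nodes.append(_NodeDraft(idx, part_index, name))
        part_has_node = True
        if branch_stack:
            branch_stack[-1].had_particle = True
        return idx

    def finalize_part(end_pos: int) -> None:
        nonlocal part_tags, ring_open
        for ctx in branch_stack:
            err(ctx.open_pos, 1, "unclosed branch")
        if expect_particle and part_has_node and pending_bond is not None:
            err(pending_bond.pos, pending_bond.length, "dangling bond separator")
        if not part_has_node:
            err(min(part_start, len(text)),
                1 if part_start < len(text) else 0, "empty part")
        for lab, (_node, tok) in sorted(ring_open.items()):
            err(tok.pos, tok.length, f"unmatched ring closure label {lab}")
        part_tags = {}
        ring_open = {}

    i = 0
    ntok = len(tokens)
    while i < ntok:
        tok = tokens[i]
        kind = tok.kind

        if kind is TokenKind.ERROR:
            err(tok.pos, tok.length, str(tok.value))

        elif kind is TokenKind.NAME or kind is TokenKind.COUNT:
            count = 1
            name_tok = tok
            if kind is TokenKind.COUNT:
                if i + 1 < ntok and tokens[i + 1].kind is TokenKind.NAME:
                    count = int(tok.value)  # type: ignore[arg-type]
                    name_tok = tokens[i + 1]
                    i += 1
                    if count < 1:
                        err(tok.pos, tok.length, "repeat count must be positive")
                        count = 1
                    elif count > MAX_REPEAT:
                        err(tok.pos, tok.length,
                            f"repeat count exceeds maximum of {MAX_REPEAT}")
                        count = 1
                else:
                    err(tok.pos, tok.length,
                        "repeat count must directly precede a particle name")
                    i += 1
                    continue
            if not expect_particle:
                err(name_tok.pos, name_tok.length,
                    "missing bond separator before particle")
            first = new_node(str(name_tok.value))
            if last is not None:
                add_bond(last, first, name_tok.pos, name_tok.length)
            prev = first
            for _ in range(count - 1):
                nxt = new_node(str(name_tok.value))
                add_bond(prev, nxt, name_tok.pos, name_tok.length)
                prev = nxt
            last = prev
            expect_particle = False
            at_branch_start = False
            pending_bond = None
            if count == 1:
                label_target = tag_target = ring_target = prev
            else:
                # repeated particles are anonymous copies: no label/tag
                label_target = tag_target = None
                ring_target = prev

        elif kind is TokenKind.LABEL:
            if label_target is None:
                err(tok.pos, tok.length,
                    "backbone label must directly follow a particle name")
            elif nodes[label_target].backbone_label is not None:
                err(tok.pos, tok.length, "duplicate backbone label")
            else:
                nodes[label_target].backbone_label = str(tok.value)
            label_target = None

        elif kind is TokenKind.TAG:
            tag = str(tok.value)
            if tag_target is None:
                err(tok.pos, tok.length,
                    f"[{tag}] tag must directly follow a particle")
            elif tag in part_tags:
                err(tok.pos, tok.length, f"duplicate [{tag}] tag in part")
            elif nodes[tag_target].tags:
                err(tok.pos, tok.length,
                    "a particle may carry at most one of [START]/[END]")
            else:
                nodes[tag_target].tags.add(tag)
                part_tags[tag] = tag_target
            label_target = None

        elif kind is TokenKind.RING:
            lab = int(tok.value)  # type: ignore[arg-type]
            if ring_target is None:
                err(tok.pos, tok.length,
                    "ring closure must follow a particle")
            elif lab in ring_open:
                other, _otok = ring_open.pop(lab)
                if other == ring_target:
                    err(tok.pos, tok.length,
                        "ring closure bonds a particle to itself")
                else:
                    add_bond(other, ring_target, tok.pos, tok.length)
            else:
                ring_open[lab] = (ring_target, tok)
            label_target = tag_target = None

        elif kind is TokenKind.BOND:
            if expect_particle:
                if at_branch_start:
                    at_branch_start = False  # optional leading "-" in a branch
                else:
                    err(tok.pos, tok.length, "dangling bond separator")
            else:
                expect_particle = True
                pending_bond = tok
            label_target = tag_target = ring_target = None

        elif kind is TokenKind.OPEN:
            if expect_particle or last is None:
                err(tok.pos, tok.length, "branch must follow a particle")
            branch_stack.append(_BranchCtx(outer_last=last, open_pos=tok.pos))
            expect_particle = True
            at_branch_start = True
            pending_bond = None
            label_target = tag_target = ring_target = None

        elif kind is TokenKind.CLOSE:
            if not branch_stack:
                err(tok.pos, tok.length, "unmatched ')'")
            else:
                ctx = branch_stack.pop()
                if not ctx.had_particle:
                    err(ctx.open_pos, tok.pos - ctx.open_pos + 1, "empty branch")
                elif expect_particle and pending_bond is not None:
                    err(pending_bond.pos, pending_bond.length,
                        "dangling bond separator before ')'")
                last = ctx.outer_last
            expect_particle = False
            at_branch_start = False
            pending_bond = None
            label_target = tag_target = ring_target = None

        elif kind is TokenKind.DOT:
            finalize_part(tok.pos)
            part_index += 1
            part_start = tok.pos + 1
            part_has_node = False
            last = None
            expect_particle = True
            at_branch_start = False
            pending_bond = None
            branch_stack = []
            label_target = tag_target = ring_target = None

        i += 1

    finalize_part(len(text))
    errors.sort(key=lambda e: (e.position, e.length))
    return nodes, bonds, part_index + 1, errors


def validate(text: str) -> ParseReport:
    """Check a string against the SPICES grammar without raising.

    All structural violations found are reported with 0-based character
    offsets; scanning continues past each error so multiple problems are
    listed in one pass.
    """
    _nodes, _bonds, _parts, errors = _scan(text)
    return ParseReport(valid=not errors, errors=tuple(errors))


def parse(text: str,
          catalog: Optional[Iterable[str]] = None) -> SpicesMolecule:
    """Parse a SPICES string into a molecule graph.

    Parameters
    ----------
    text:
        The line notation.
    catalog:
        Optional collection of allowed particle names; any name outside it
        raises :class:`UnknownParticleError`.

    Raises
    ------
    SpicesSyntaxError
        On the first grammar violation (the attached report lists all of
        them).
    """
    drafts, bonds, parts, errors = _scan(text)
    if errors:
        raise SpicesSyntaxError(ParseReport(valid=False, errors=tuple(errors)))
    if catalog is not None:
        allowed = set(catalog)
        offset = 0
        for d in drafts:
            if d.name not in allowed:
                pos = text.find(d.name, offset)
                raise UnknownParticleError(d.name, max(pos, 0))
    nodes = tuple(ParticleNode(d.index, d.part_index, d.name,
                               d.backbone_label, frozenset(d.tags))
                  for d in drafts)
    return SpicesMolecule(nodes=nodes, bonds=frozenset(bonds),
                          parts=parts, source_text=text)


# ---------------------------------------------------------------------------
# Invariant checking and serialization
# ---------------------------------------------------------------------------

def check_molecule(mol: SpicesMolecule) -> None:
    """Raise :class:`StructureError` if ``mol`` violates any invariant."""
    n = len(mol.nodes)
    for i, node in enumerate(mol.nodes):
        if node.index != i:
            raise StructureError(f"node index {node.index} at position {i}: "
                                 "indices must be consecutive in order")
        if not _NAME_RE.match(node.name):
            raise StructureError(f"invalid particle name '{node.name}'")
        if node.backbone_label is not None:
            lab = node.backbone_label
            if not lab or "'" in lab or not lab.isascii() or not lab.isprintable():
                raise StructureError(f"invalid backbone label '{lab}'")
        if not node.tags <= {"START", "END"}:
            raise StructureError(f"invalid tags {set(node.tags)}")
        if len(node.tags) > 1:
            raise StructureError("a particle may carry at most one tag")
        if not 0 <= node.part_index < mol.parts:
            raise StructureError("part index out of range")
    prev_part = 0
    for node in mol.nodes:
        if node.part_index not in (prev_part, prev_part + 1):
            raise StructureError("part indices must be non-decreasing "
                                 "and consecutive in notation order")
        prev_part = node.part_index
    if n and prev_part != mol.parts - 1:
        raise StructureError("part count does not match node part indices")
    for bond in mol.bonds:
        i, j = bond
        if not (0 <= i < n and 0 <= j < n):
            raise StructureError(f"bond {bond} references invalid node index")
        if i >= j:
            raise StructureError(f"bond {bond} must be a sorted pair")
        if mol.nodes[i].part_index != mol.nodes[j].part_index:
            raise StructureError(f"bond {bond} spans two parts")
    adj = mol.adjacency()
    for p in range(mol.parts):
        members = mol.part_node_indices(p)
        if not members:
            raise StructureError(f"part {p} is empty")
        seen = {members[0]}
        stack = [members[0]]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != len(members):
            raise StructureError(f"part {p} is not connected")
        for tag in ("START", "END"):
            if sum(1 for m in members if tag in mol.nodes[m].tags) > 1:
                raise StructureError(f"part {p} has more than one [{tag}] tag")


def _node_token(node: ParticleNode, rings: Sequence[int]) -> str:
    out = node.name
    if node.backbone_label is not None:
        out += f"'{node.backbone_label}'"
    for tag in node.tags:  # at most one
        out += f"[{tag}]"
    for lab in rings:
        out += f"[{lab}]"
    return out


def serialize(mol: SpicesMolecule) -> str:
    """Write a molecule back to SPICES notation.

    The notation is not canonically unique and no canonicalization is
    attempted: the output is a spanning-tree traversal from each part's
    first node, with non-tree bonds emitted as ring closures.  It is
    guaranteed that ``parse(serialize(mol))`` is graph-isomorphic to
    ``mol`` with identical names, labels, tags and part count.
    """
    check_molecule(mol)
    adj = mol.adjacency()
    pieces: list[str] = []
    for p in range(mol.parts):
        members = mol.part_node_indices(p)
        root = members[0]
        # spanning DFS: tree children + ring (back) bonds
        parent: dict[int, Optional[int]] = {root: None}
        children: dict[int, list[int]] = {m: [] for m in members}
        ring_bonds: list[tuple[int, int]] = []
        seen_ring: set[tuple[int, int]] = set()
        stack = [root]
        visited = {root}
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            for w in sorted(adj[v], reverse=True):
                if w not in visited:
                    visited.add(w)
                    parent[w] = v
                    children[v].append(w)
                    stack.append(w)
                else:
                    key = (v, w) if v < w else (w, v)
                    if w != parent[v] and key not in seen_ring:
                        seen_ring.add(key)
                        ring_bonds.append(key)
        # children were appended in reverse-sorted order; restore ascending
        for v in children:
            children[v].sort()
        ring_labels: dict[int, list[int]] = {m: [] for m in members}
        for lab, (a, b) in enumerate(sorted(ring_bonds), start=1):
            ring_labels[a].append(lab)
            ring_labels[b].append(lab)
        out: list[str] = []
        emit: list[tuple[str, object]] = [("node", root)]
        while emit:
            what, x = emit.pop()
            if what == "text":
                out.append(x)  # type: ignore[arg-type]
            else:
                v = x  # type: ignore[assignment]
                out.append(_node_token(mol.nodes[v], ring_labels[v]))
                ch = children[v]
                if ch:
                    pushes: list[tuple[str, object]] = []
                    for c in ch[:-1]:
                        pushes += [("text", "(-"), ("node", c), ("text", ")")]
                    pushes += [("text", "-"), ("node", ch[-1])]
                    emit.extend(reversed(pushes))
        pieces.append("".join(out))
    return ".".join(pieces)


# ---------------------------------------------------------------------------
# Plain-text external interfaces
# ---------------------------------------------------------------------------

def iter_spices_file(source) -> Iterator[tuple[int, str]]:
    """Yield ``(line_number, spices_string)`` from a batch file.

    One molecule per line; blank lines and ``#``-prefixed comment lines are
    skipped.  ``source`` is a path or an open text file.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source, "r", encoding="ascii")
        close = True
    else:
        fh = source
    try:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped
    finally:
        if close:
            fh.close()


def read_particle_catalog(source) -> dict[str, str]:
    """Read a two-column tab-separated particle catalog (name, description).

    Blank lines and ``#`` comments are skipped; a line without a tab yields
    a particle with an empty description.  Invalid particle names raise
    :class:`StructureError`.
    """
    catalog: dict[str, str] = {}
    for lineno, line in iter_spices_file(source):
        name, _sep, desc = line.partition("\t")
        name = name.strip()
        if not _NAME_RE.match(name):
            raise StructureError(
                f"line {lineno}: invalid particle name '{name}' in catalog")
        catalog[name] = desc.strip()
    return catalog
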