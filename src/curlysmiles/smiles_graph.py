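"""Molecular-graph construction from (annotated) SMILES components.

The SMILES dialect implemented here follows the standard language with
three changes: the wildcard atom ``*`` must always be written as a
square-bracket atomic code (SQC); ``~`` (unspecified bond) and ``$``
(quadruple bond) are bond symbols whose endpoints must both be SQC-encoded;
and the stereo glyphs ``@``, ``/``, ``\\`` are rejected outright because
stereochemistry is expressed through stereodescriptor annotations instead.

Curly-brace annotation blocks are consumed during the scan and anchored to
the nearest preceding atomic node (only ring-closure digits may intervene)
or, for state/shape and miscellaneous markers, to the component as a whole.

Parsing records an emission plan (token stream) so that serialization
reproduces the source byte-for-byte; graphs built programmatically (e.g. by
repeat-unit expansion) are serialized by a generic depth-first writer
instead.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable

from .annotation_model import (
    COMPONENT,
    Annotation,
    MarkerClass,
    parse_annotation,
    resolve_relative_pointer,
)
from .elements import (
    AROMATIC_BARE,
    AROMATIC_BRACKET,
    ORGANIC_SUBSET,
    STANDARD_VALENCES,
    is_element,
)
from .errors import (
    BondEndpointError,
    BranchError,
    NotationError,
    RingClosureError,
    SqcError,
    StereoGlyphError,
    UnknownElementError,
    AmbiguousBondWarning,
)

BOND_CHARS = "-=#$:~&"

#: Human-readable names for bond symbols.
ORDER_NAMES = {
    "-": "single", "=": "double", "#": "triple", "$": "quadruple",
    ":": "aromatic", "~": "unspecified", "&": "ambiguous",
}

#: Numeric bond orders used when materializing implicit hydrogens.
_ORDER_VALUE = {"-": 1, "=": 2, "#": 3, "$": 4, ":": 1.5, "~": 1, "&": 1}

_STEREO_GLYPHS = set("@/\\")


@dataclass
class AtomNode:
    """One atomic node in order of appearance."""

    index: int
    symbol: str              # canonical element symbol, or "*"
    aromatic: bool = False
    is_sqc: bool = False
    isotope: int | None = None
    hcount: int | None = None   # None = implicit (bare organic-subset atom)
    charge: int = 0
    annotations: list[Annotation] = field(default_factory=list)
    sqc_raw: str | None = None  # bracket interior as written, for round-trip

    def copy(self, index: int) -> "AtomNode":
        a = AtomNode(index=index, symbol=self.symbol, aromatic=self.aromatic,
                     is_sqc=self.is_sqc, isotope=self.isotope,
                     hcount=self.hcount, charge=self.charge,
                     sqc_raw=self.sqc_raw)
        a.annotations = [Annotation(x.marker_class, x.marker,
                                    list(x.entries), index)
                         for x in self.annotations]
        return a


@dataclass
class BondEdge:
    """An edge between two atomic nodes.

    ``symbol`` is the effective bond symbol; ``explicit`` records whether it
    was written in the source (default single/aromatic bonds are implicit).
    """

    a: int
    b: int
    symbol: str = "-"
    explicit: bool = False
    from_ring_closure: bool = False

    @property
    def order_name(self) -> str:
        return ORDER_NAMES[self.symbol]


@dataclass
class MolecularGraph:
    """Atoms in appearance order, bonds, and component-anchored annotations."""

    atoms: list[AtomNode] = field(default_factory=list)
    bonds: list[BondEdge] = field(default_factory=list)
    component_annotations: list[Annotation] = field(default_factory=list)
    tokens: list[tuple] | None = None  # emission plan from the parser

    def degree_sum(self, idx: int) -> float:
        return sum(_ORDER_VALUE[b.symbol]
                   for b in self.bonds if idx in (b.a, b.b))

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == idx:
                out.append(b.b)
            elif b.b == idx:
                out.append(b.a)
        return out

    def all_annotations(self) -> list[Annotation]:
        anns: list[Annotation] = []
        for a in self.atoms:
            anns.extend(a.annotations)
        anns.extend(self.component_annotations)
        return anns

    def implicit_hydrogens(self, idx: int) -> int:
        """Materialize the implicit H count of a bare organic-subset atom.

        Uses the smallest standard valence that accommodates the explicit
        bond-order sum (aromatic bonds count 1.5); boundary and substitution
        annotations consume one valence each, since they stand for an open
        bond or a replaced hydrogen.
        """
        import math

        atom = self.atoms[idx]
        if atom.hcount is not None:
            return atom.hcount
        if atom.symbol == "*":
            return 0
        open_bonds = sum(
            1 for ann in atom.annotations
            if ann.marker_class is MarkerClass.UNIT
            or (ann.marker_class is MarkerClass.OPAM
                and ann.marker[1] in "RXYnr")
            or (ann.marker_class is MarkerClass.GEAM
                and ann.marker != ".|" and ann.marker[1] in "|YRX")
        )
        used = math.ceil(self.degree_sum(idx)) + open_bonds
        valences = STANDARD_VALENCES.get(atom.symbol, (0,))
        if atom.aromatic:
            # no promotion to a higher valence inside an aromatic system:
            # a three-connected aromatic N is pyrrole-like and carries no H
            return max(0, valences[0] - used)
        for v in valences:
            if v >= used:
                return v - used
        return 0


# --------------------------------------------------------------------------
# square-bracket atomic codes

_SQC_RE = re.compile(
    r"""^(?P<isotope>\d+)?
         (?P<symbol>\*|[A-Z][a-z]?|[a-z]{1,2})
         (?P<hydrogens>H\d*)?
         (?P<charge>\+\d+|-\d+|\++|-+)?$""",
    re.VERBOSE,
)


def parse_sqc(token: str, pos: int = 0) -> AtomNode:
    """Parse the interior of one ``[...]`` atomic code.

    Field order follows the standard SQC layout: isotope digits, atomic
    symbol (or wildcard), hydrogen count, charge.
    """
    if not token:
        raise SqcError("empty square-bracket atomic code", pos=pos)
    for g in _STEREO_GLYPHS:
        if g in token:
            raise StereoGlyphError(
                "stereodescriptive symbols @, / and \\ are not accepted; "
                "use stereodescriptor annotations such as {R}", pos=pos
            )
    m = _SQC_RE.match(token)
    if m is None:
        raise SqcError(f"malformed atomic code [{token}]", pos=pos)
    sym = m.group("symbol")
    aromatic = False
    if sym != "*":
        if sym[0].islower():
            if sym not in AROMATIC_BRACKET:
                raise UnknownElementError(
                    f"{sym!r} may not be written lowercase", pos=pos)
            aromatic = True
            sym = sym.capitalize()
        if not is_element(sym):
            raise UnknownElementError(f"unknown element {sym!r}", pos=pos)
    hcount = 0
    h = m.group("hydrogens")
    if h is not None:
        hcount = int(h[1:]) if len(h) > 1 else 1
    charge = 0
    c = m.group("charge")
    if c is not None:
        if c in ("+", "-") or c[1:].isdigit():
            charge = int(c) if c[1:].isdigit() else (1 if c == "+" else -1)
        else:  # ++ / -- style
            charge = len(c) if c[0] == "+" else -len(c)
    return AtomNode(index=-1, symbol=sym if sym != "*" else "*",
                    aromatic=aromatic, is_sqc=True,
                    isotope=int(m.group("isotope")) if m.group("isotope")
                    else None,
                    hcount=hcount, charge=charge, sqc_raw=token)


def emit_atom(a: AtomNode) -> str:
    """Serialize one atomic node code."""
    if not a.is_sqc:
        return a.symbol.lower() if a.aromatic else a.symbol
    if a.sqc_raw is not None:
        return f"[{a.sqc_raw}]"
    parts = []
    if a.isotope is not None:
        parts.append(str(a.isotope))
    if a.symbol == "*":
        parts.append("*")
    else:
        parts.append(a.symbol.lower() if a.aromatic else a.symbol)
    h = a.hcount or 0
    if h == 1:
        parts.append("H")
    elif h > 1:
        parts.append(f"H{h}")
    if a.charge:
        sign = "+" if a.charge > 0 else "-"
        parts.append(sign if abs(a.charge) == 1 else f"{sign}{abs(a.charge)}")
    return "[" + "".join(parts) + "]"


# --------------------------------------------------------------------------
# component parsing

AnnotationHook = Callable[[str, str, int], Annotation]


def _default_hook(block: str, context: str, pos: int) -> Annotation:
    return parse_annotation(block, context=context, pos=pos)


def _matching_brace(text: str, i: int) -> int:
    depth = 0
    for j in range(i, len(text)):
        if text[j] == "{":
            depth += 1
        elif text[j] == "}":
            depth -= 1
            if depth == 0:
                return j
    raise NotationError("unclosed '{'", pos=i)


def _only_blocks_remain(text: str, i: int) -> bool:
    """True if text[i:] consists solely of balanced ``{...}`` blocks."""
    while i < len(text):
        if text[i] != "{":
            return False
        i = _matching_brace(text, i) + 1
    return True


def parse_plain_smiles(text: str,
                       annotation_hook: AnnotationHook | None = None,
                       pos: int = 0) -> MolecularGraph:
    """Parse a SMILES-form component into a :class:`MolecularGraph`.

    ``annotation_hook`` receives each curly-brace block (interior text, the
    anchoring context ``atom``/``end``/``component``, and its offset) and
    returns the parsed :class:`Annotation`; by default the built-in
    annotation parser is used.
    """
    hook = annotation_hook or _default_hook
    g = MolecularGraph(tokens=[])
    stack: list[int] = []
    last_atom: int | None = None
    pending: str | None = None
    pending_pos = 0
    ring_open: dict[str, tuple[int, str | None, int]] = {}
    # anchoring state: can the next annotation still attach to last_atom?
    anchor_ok = False
    # ring digits must directly follow an atom (or its other ring digits),
    # optionally via one bond symbol
    ring_ok = False
    caa_seen = False

    def add_bond(a: int, b: int, symbol: str | None, *, ring: bool,
                 at: int) -> None:
        if a == b:
            raise RingClosureError("ring bond closes onto its own atom",
                                   pos=at)
        if symbol is None:
            both_arom = g.atoms[a].aromatic and g.atoms[b].aromatic
            bond = BondEdge(a, b, ":" if both_arom else "-", explicit=False,
                            from_ring_closure=ring)
        else:
            bond = BondEdge(a, b, symbol, explicit=True,
                            from_ring_closure=ring)
        if bond.symbol in "~$":
            for idx in (a, b):
                if not g.atoms[idx].is_sqc:
                    raise BondEndpointError(
                        f"atoms joined by a {bond.symbol!r} bond must be "
                        "square-bracket encoded", pos=at)
        g.bonds.append(bond)

    def new_atom(atom: AtomNode, at: int) -> None:
        nonlocal last_atom, pending, anchor_ok, ring_ok
        atom.index = len(g.atoms)
        g.atoms.append(atom)
        g.tokens.append(("atom", atom.index))
        if last_atom is not None:
            add_bond(last_atom, atom.index, pending, ring=False, at=at)
        elif pending is not None:
            raise NotationError("bond symbol with no preceding atom",
                                pos=pending_pos)
        pending = None
        last_atom = atom.index
        anchor_ok = True
        ring_ok = True

    def close_ring(label: str, at: int) -> None:
        nonlocal pending
        if last_atom is None:
            raise RingClosureError("ring-closure digit with no preceding "
                                   "atom", pos=at)
        if label in ring_open:
            a, sym_a, _ = ring_open.pop(label)
            sym = None
            if sym_a is not None and pending is not None and sym_a != pending:
                raise RingClosureError(
                    f"ring bond {label} opened with {sym_a!r} but closed "
                    f"with {pending!r}", pos=at)
            sym = sym_a if sym_a is not None else pending
            add_bond(a, last_atom, sym, ring=True, at=at)
        else:
            ring_open[label] = (last_atom, pending, at)
        pending = None

    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        at = pos + i
        if ch in _STEREO_GLYPHS:
            raise StereoGlyphError(
                "stereodescriptive symbols @, / and \\ are not accepted; "
                "use stereodescriptor annotations such as {R}", pos=at)
        if ch == "{":
            j = _matching_brace(text, i)
            block = text[i + 1 : j]
            at_end = _only_blocks_remain(text, j + 1)
            if caa_seen or not anchor_ok:
                if not at_end:
                    raise NotationError(
                        "annotation is not anchored to an atomic node",
                        pos=at)
                context = "component"
            else:
                context = "end" if at_end else "atom"
            ann = hook(block, context, at + 1)
            if ann.anchor == COMPONENT:
                caa_seen = True
                g.component_annotations.append(ann)
            else:
                if last_atom is None:
                    raise NotationError(
                        "annotation with no atomic node to anchor to", pos=at)
                ann.anchor = last_atom
                g.atoms[last_atom].annotations.append(ann)
            g.tokens.append(("ann", ann))
            ring_ok = False
            i = j + 1
            continue
        if ch in BOND_CHARS:
            if pending is not None:
                raise NotationError("two consecutive bond symbols", pos=at)
            if last_atom is None:
                raise NotationError("bond symbol with no preceding atom",
                                    pos=at)
            if ch == "&":
                warnings.warn(
                    "'&' stored as an ambiguous bond; its chemical meaning "
                    "is not defined", AmbiguousBondWarning, stacklevel=2)
            pending = ch
            pending_pos = at
            g.tokens.append(("lit", ch))
            anchor_ok = False
            i += 1
            continue
        if ch.isdigit() or ch == "%":
            if not ring_ok:
                raise RingClosureError(
                    "ring-closure digit must directly follow an atomic node",
                    pos=at)
            if ch == "%":
                if i + 2 >= n or not text[i + 1 : i + 3].isdigit():
                    raise RingClosureError("'%' needs two digits", pos=at)
                label = text[i + 1 : i + 3]
                lit = text[i : i + 3]
                i += 3
            else:
                label = ch
                lit = ch
                i += 1
            # the bond symbol token, if any, was already emitted
            close_ring(label, at)
            g.tokens.append(("lit", lit))
            continue
        if ch == "(":
            if last_atom is None:
                raise BranchError("branch with no preceding atom", pos=at)
            if pending is not None:
                raise BranchError("bond symbol before '('", pos=at)
            stack.append(last_atom)
            g.tokens.append(("lit", "("))
            anchor_ok = False
            ring_ok = False
            i += 1
            continue
        if ch == ")":
            if not stack:
                raise BranchError("unmatched ')'", pos=at)
            if pending is not None:
                raise BranchError("dangling bond symbol before ')'", pos=at)
            if last_atom == stack[-1]:
                raise BranchError("empty branch", pos=at)
            last_atom = stack.pop()
            g.tokens.append(("lit", ")"))
            anchor_ok = False
            ring_ok = False
            i += 1
            continue
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise NotationError("unclosed '['", pos=at)
            atom = parse_sqc(text[i + 1 : j], pos=at + 1)
            new_atom(atom, at)
            i = j + 1
            continue
        if ch == "*":
            raise BondEndpointError(
                "the atomic wildcard must be square-bracket encoded ([*])",
                pos=at)
        if ch.isupper():
            sym = None
            if text[i : i + 2] in ("Cl", "Br"):
                sym = text[i : i + 2]
            elif ch in "BCNOPSFI":
                sym = ch
            if sym is None:
                if is_element(ch) or is_element(text[i : i + 2].capitalize()):
                    raise UnknownElementError(
                        f"element at {ch!r} is outside the organic subset "
                        "and must be square-bracket encoded", pos=at)
                raise UnknownElementError(f"unknown symbol {ch!r}", pos=at)
            new_atom(AtomNode(index=-1, symbol=sym), at)
            i += len(sym)
            continue
        if ch in AROMATIC_BARE:
            new_atom(AtomNode(index=-1, symbol=ch.upper(), aromatic=True), at)
            i += 1
            continue
        raise NotationError(f"unexpected character {ch!r}", pos=at)

    if pending is not None:
        raise NotationError("trailing bond symbol", pos=pending_pos)
    if stack:
        raise BranchError("unclosed branch", pos=pos)
    if ring_open:
        label, (_, _, where) = next(iter(ring_open.items()))
        raise RingClosureError(f"ring bond {label} never closed", pos=where)
    if not g.atoms:
        raise NotationError("component contains no atomic node", pos=pos)
    return g


def validate_pointers(g: MolecularGraph) -> None:
    """Resolve every relative node pointer in the graph, raising on dangling
    ones.  Kept separate from parsing: a fragment like ``O{-|i=-2}`` is a
    legal notation on its own even though its pointer only resolves in the
    context of the full component it was cut from."""
    for atom in g.atoms:
        for ann in atom.annotations:
            if (ann.marker_class is MarkerClass.GEAM
                    and ann.entry("i") is not None):
                resolve_relative_pointer(ann, g)


# --------------------------------------------------------------------------
# serialization

def serialize_graph(g: MolecularGraph, annotations: bool = True) -> str:
    """Serialize a graph back to a SMILES-form component string.

    Graphs produced by the parser replay their recorded emission plan, so
    parse -> serialize is byte-identical; constructed graphs fall back to a
    depth-first writer whose output re-parses to an isomorphic graph.  With
    ``annotations=False`` every curly-brace block is omitted, leaving the
    plain SMILES skeleton.
    """
    tokens = g.tokens if g.tokens is not None else _plan_tokens(g)
    out: list[str] = []
    for kind, val in tokens:
        if kind == "atom":
            out.append(emit_atom(g.atoms[val]))
        elif kind == "lit":
            out.append(val)
        elif annotations:
            out.append(val.source())
    return "".join(out)


def _plan_tokens(g: MolecularGraph) -> list[tuple]:
    """Build an emission plan for a graph that has none (generic DFS writer)."""
    import sys

    bond_of: dict[frozenset, BondEdge] = {
        frozenset((b.a, b.b)): b for b in g.bonds
    }
    adj: dict[int, list[int]] = {a.index: [] for a in g.atoms}
    for b in g.bonds:
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)
    for v in adj.values():
        v.sort()

    # spanning DFS in index order; non-tree edges become ring closures
    tree: dict[int, list[int]] = {a.index: [] for a in g.atoms}
    parent: dict[int, int | None] = {}
    for root in [a.index for a in g.atoms]:
        if root in parent:
            continue
        stack2: list[tuple[int, int | None]] = [(root, None)]
        while stack2:
            node, par = stack2.pop()
            if node in parent:
                continue
            parent[node] = par
            if par is not None:
                tree[par].append(node)
            for nb in sorted(adj[node], reverse=True):
                if nb not in parent:
                    stack2.append((nb, node))
    tree_edges = {frozenset((c, p)) for p, cs in tree.items() for c in cs}
    ring_labels: dict[frozenset, str] = {}
    for n, b in enumerate(b for b in g.bonds
                          if frozenset((b.a, b.b)) not in tree_edges):
        lab = n + 1
        ring_labels[frozenset((b.a, b.b))] = (
            str(lab) if lab < 10 else f"%{lab:02d}"
        )

    tokens: list[tuple] = []

    def bond_lit(b: BondEdge) -> str:
        if not b.explicit:
            return ""
        if b.symbol == ":" and g.atoms[b.a].aromatic and g.atoms[b.b].aromatic:
            return ""
        return b.symbol

    ring_opened: set[frozenset] = set()

    def write(node: int, par: int | None) -> None:
        if par is not None:
            lit = bond_lit(bond_of[frozenset((par, node))])
            if lit:
                tokens.append(("lit", lit))
        tokens.append(("atom", node))
        for e, lab in ring_labels.items():
            if node in e:
                if e not in ring_opened:
                    ring_opened.add(e)
                    lit = bond_lit(bond_of[e])
                    if lit:
                        tokens.append(("lit", lit))
                tokens.append(("lit", lab))
        for ann in g.atoms[node].annotations:
            tokens.append(("ann", ann))
        children = tree[node]
        for k, child in enumerate(children):
            if k < len(children) - 1:
                tokens.append(("lit", "("))
                write(child, node)
                tokens.append(("lit", ")"))
            else:
                write(child, node)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * len(g.atoms) + 100))
    try:
        for r in [a.index for a in g.atoms if parent.get(a.index) is None]:
            write(r, None)
    finally:
        sys.setrecursionlimit(old_limit)
    for ann in g.component_annotations:
        tokens.append(("ann", ann))
    return tokens
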