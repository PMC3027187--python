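"""Structure-level rewrites.

* multiplier expansion (shorthand -> exhaustive notation),
* repeat-unit expansion of ``+r``-annotated macrocycles and
  ``+n``-annotated linear chains into explicit graphs,
* annotation stripping down to plain SMILES (with a strict mode that
  refuses when annotations carry chemical identity — a methyl *group*
  ``C{-}`` must not silently become the methyl *radical* ``[CH3]``),
* molecular-formula derivation from a graph, comparable against
  stoichiometric formula notations.
"""

from __future__ import annotations

import copy
import enum

from .annotation_model import Annotation, MarkerClass
from .errors import NotationError, StrictStripError
from .lexer import Form, RawComponent
from .notation import ParsedComponent, ParsedNotation
from .sfn import SFNComposition, composition_from_counts
from .smiles_graph import AtomNode, BondEdge, MolecularGraph, serialize_graph


class StripPolicy(enum.Enum):
    DROP = "drop"      # delete every annotation
    STRICT = "strict"  # refuse if any annotation changes chemical meaning


#: Annotation classes whose removal alters what the notation denotes.
_IDENTITY_CLASSES = frozenset(
    {MarkerClass.UNIT, MarkerClass.GEAM, MarkerClass.OPAM}
)


def expand_multipliers(pn: ParsedNotation) -> ParsedNotation:
    """Replace each component with multiplier m by m copies with multiplier 1.

    Serializing the result yields the exhaustive notation.
    """
    out = ParsedNotation()
    for pc in pn.components:
        for _ in range(pc.multiplier):
            rc = RawComponent(text=pc.raw.text, form=pc.raw.form,
                              multiplier=1, offset=pc.raw.offset)
            out.components.append(ParsedComponent(raw=rc, body=pc.body))
    return out


def _find_single(g: MolecularGraph, pred) -> tuple[int, Annotation] | None:
    found = None
    for atom in g.atoms:
        for ann in atom.annotations:
            if pred(ann):
                if found is not None:
                    return -1, ann  # sentinel: more than one
                found = (atom.index, ann)
    return found


def _copy_unit(g: MolecularGraph, offset: int,
               drop: set[tuple[int, str]]) -> tuple[list[AtomNode],
                                                    list[BondEdge]]:
    """Copy atoms/bonds with shifted indices, dropping listed annotations
    ((atom index, marker) pairs)."""
    atoms = []
    for a in g.atoms:
        c = a.copy(a.index + offset)
        c.annotations = [ann for ann in c.annotations
                         if (a.index, ann.marker) not in drop]
        atoms.append(c)
    bonds = [BondEdge(b.a + offset, b.b + offset, b.symbol, b.explicit,
                      b.from_ring_closure) for b in g.bonds]
    return atoms, bonds


def expand_ring_repeat(g: MolecularGraph, k: int | None = None
                       ) -> MolecularGraph:
    """Expand a repeat unit with one boundary and one ``+r`` annotation into
    an explicit macrocycle of k units.

    The open bond at each copy's ``+r`` atom joins the boundary atom of the
    next copy, and the last copy closes back onto the first, so the k join
    bonds are the final k bonds of the returned graph.  The join bond order
    comes from the boundary descriptor; all other annotations are copied
    onto every unit.
    """
    plus = _find_single(
        g, lambda a: a.marker_class is MarkerClass.OPAM and a.marker == "+r")
    if plus is None:
        raise NotationError("no '+r' repetition annotation in the unit")
    if plus[0] == -1:
        raise NotationError("more than one '+r' annotation in the unit")
    plus_idx, plus_ann = plus
    if k is None:
        entry = plus_ann.entry("n")
        if entry is None or not isinstance(entry.parsed_value, int):
            raise NotationError(
                "'+r' annotation has no integer n entry and no count was "
                "supplied")
        k = entry.parsed_value
    if k < 2:
        raise NotationError("a macrocycle needs a repeat count of at least 2")

    unit = _find_single(
        g, lambda a: a.marker_class is MarkerClass.UNIT and a.anchor != plus_idx)
    if unit is None:
        raise NotationError("no structural-unit boundary annotation in the "
                            "unit")
    if unit[0] == -1:
        raise NotationError("more than one boundary annotation in the unit")
    unit_idx, unit_ann = unit
    join_symbol = unit_ann.marker
    for ann in g.atoms[plus_idx].annotations:
        if ann.marker_class is MarkerClass.UNIT and ann.marker != join_symbol:
            raise NotationError(
                f"incompatible boundary bond symbols {join_symbol!r} and "
                f"{ann.marker!r}")

    n_atoms = len(g.atoms)
    drop = {(unit_idx, unit_ann.marker), (plus_idx, plus_ann.marker)}
    out = MolecularGraph()
    for j in range(k):
        atoms, bonds = _copy_unit(g, j * n_atoms, drop)
        out.atoms.extend(atoms)
        out.bonds.extend(bonds)
    for j in range(k):
        a = j * n_atoms + plus_idx
        b = ((j + 1) % k) * n_atoms + unit_idx
        out.bonds.append(BondEdge(a, b, join_symbol,
                                  explicit=join_symbol != "-",
                                  from_ring_closure=(j == k - 1)))
    return out


def expand_chain_repeat(g: MolecularGraph, k: int | None = None
                        ) -> MolecularGraph:
    """Expand a ``+n``-annotated repeat unit into a linear chain of k units.

    ``k`` must be supplied when the annotation carries no ``n=`` entry (an
    open-ended macromolecule).  The terminal open bonds stay dangling and
    are marked with structural-unit boundary annotations.
    """
    plus = _find_single(
        g, lambda a: a.marker_class is MarkerClass.OPAM and a.marker == "+n")
    if plus is None:
        raise NotationError("no '+n' repetition annotation in the unit")
    if plus[0] == -1:
        raise NotationError("more than one '+n' annotation in the unit")
    plus_idx, plus_ann = plus
    if k is None:
        entry = plus_ann.entry("n")
        if entry is not None and isinstance(entry.parsed_value, int):
            k = entry.parsed_value
        else:
            raise NotationError(
                "open-ended macromolecule: supply an explicit repeat count")
    if k < 1:
        raise NotationError("repeat count must be positive")

    unit = _find_single(
        g, lambda a: a.marker_class is MarkerClass.UNIT and a.anchor != plus_idx)
    if unit is not None and unit[0] == -1:
        raise NotationError("more than one boundary annotation in the unit")
    head_idx = unit[0] if unit else 0
    join_symbol = unit[1].marker if unit else "-"

    n_atoms = len(g.atoms)
    out = MolecularGraph()
    for j in range(k):
        drop = {(plus_idx, plus_ann.marker)}
        if unit and j > 0:
            drop.add((head_idx, unit[1].marker))  # consumed by the join
        atoms, bonds = _copy_unit(g, j * n_atoms, drop)
        out.atoms.extend(atoms)
        out.bonds.extend(bonds)
    for j in range(k - 1):
        a = j * n_atoms + plus_idx
        b = (j + 1) * n_atoms + head_idx
        out.bonds.append(BondEdge(a, b, join_symbol,
                                  explicit=join_symbol != "-"))
    # the final copy's repeat atom keeps a dangling boundary
    tail = (k - 1) * n_atoms + plus_idx
    out.atoms[tail].annotations.append(
        Annotation(MarkerClass.UNIT, join_symbol, anchor=tail))
    return out


def strip_annotations(pn: ParsedNotation,
                      policy: StripPolicy = StripPolicy.DROP) -> str:
    """Reduce a notation to a plain SMILES string.

    Multipliers are expanded (plain SMILES has no shorthand), annotations
    are deleted.  Under :attr:`StripPolicy.STRICT`, any boundary, group
    environment or operational annotation aborts the strip with an error
    listing the offenders, since deleting those changes what the notation
    denotes.
    """
    if isinstance(policy, str):
        policy = StripPolicy(policy)
    offenders: list[str] = []
    for pc in pn.components:
        if pc.form is not Form.SMILES_FORM:
            raise NotationError(
                f"component {pc.raw.text!r} has no plain-SMILES reading")
        if policy is StripPolicy.STRICT:
            offenders.extend(
                ann.source() for ann in pc.body.all_annotations()
                if ann.marker_class in _IDENTITY_CLASSES
            )
    if offenders:
        raise StrictStripError(
            "stripping would change chemical identity; offending "
            "annotations: " + ", ".join(offenders))
    parts = []
    for pc in expand_multipliers(pn).components:
        parts.append(serialize_graph(pc.body, annotations=False))
    return ".".join(parts)


def molecular_formula(g: MolecularGraph) -> SFNComposition:
    """Derive the elemental composition of a graph, hydrogens included.

    Implicit hydrogens on bare organic-subset atoms are materialized from
    the standard-valence table; the net charge is the sum of atomic
    charges.  Wildcard atoms make the formula undefined.
    """
    counts: dict[str, int] = {}
    hydrogens = 0
    charge = 0
    for atom in g.atoms:
        if atom.symbol == "*":
            raise NotationError(
                "molecular formula undefined: graph contains wildcard atoms")
        key = (f"^{atom.isotope}{atom.symbol}" if atom.isotope
               else atom.symbol)
        counts[key] = counts.get(key, 0) + 1
        if atom.hcount is not None:
            hydrogens += atom.hcount
        else:
            hydrogens += g.implicit_hydrogens(atom.index)
        charge += atom.charge
    if hydrogens:
        counts["H"] = counts.get("H", 0) + hydrogens
    return composition_from_counts(counts, charge)
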