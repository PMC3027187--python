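"""Typed annotation blocks: markers, dictionaries, anchoring, pointers.

An annotation is the text between one ``{}`` pair inside a SMILES-form
component.  Single-character annotations are stereodescriptors (D, E, L, R,
S, Z) or structural-unit boundary descriptors (a bond symbol marking an open
bond).  Every other annotation opens with a two-character annotation marker
(AM) followed by an optional ``key=value;...`` dictionary:

* GEAM — group environment (bond symbol or dot first, e.g. ``-|`` for
  surface attachment, ``-R`` for an alkyl substituent, ``=Y`` for a generic
  double-bonded neighbor, ``.|`` for ionic surface interaction);
* MDAM — molecular detail, ``!`` + one of a/p/m/r/H/I (anchor atom, pair,
  multiplet, ring, hydrogen bonding, non-H interaction);
* OPAM — operational, ``+`` + R/X/Y/L (formal substitution or ligand
  addition) or n/r (linear-chain / ring repetition of the annotated unit);
* SSAM — state and shape, two lowercase letters, component-anchored;
* MIAM — miscellaneous interest, any other two-letter marker,
  component-anchored.

Dictionary values may themselves be complete notations (key ``c``), making
the language recursive.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Any

from .errors import (
    AnnotationError,
    DictionaryError,
    PointerError,
    UnknownKeyWarning,
    UnknownMarkerWarning,
)

if TYPE_CHECKING:  # pragma: no cover
    from .smiles_graph import MolecularGraph

STEREO_LETTERS = frozenset("DELRSZ")
BOND_SYMBOLS = frozenset("-=#:&~")
_KEY_RE = re.compile(r"^[A-Za-z$][A-Za-z_]*$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")

#: Anchor sentinel for component-anchored annotations.
COMPONENT = "component"


class MarkerClass(enum.Enum):
    STEREO = "stereo"
    UNIT = "unit"
    GEAM = "geam"
    MDAM = "mdam"
    OPAM = "opam"
    SSAM = "ssam"
    MIAM = "miam"


#: Marker classes anchored to an atomic node (directly after its ANC plus
#: any ring-closure digits); SSAM/MIAM anchor to the whole component.
ATOM_CLASSES = frozenset(
    {MarkerClass.STEREO, MarkerClass.UNIT, MarkerClass.GEAM,
     MarkerClass.MDAM, MarkerClass.OPAM}
)


@dataclass
class DictEntry:
    """One ``key=value`` pair of an annotation dictionary.

    ``customer`` marks ``$``-prefixed keys, which are user-defined and never
    validated against the seed key registry.  ``parsed_value`` holds a typed
    reading of the raw value when one applies: an int, an inclusive integer
    range ``(lo, hi)``, a charge token (+1/-1), or a recursively parsed
    notation for the ligand key ``c``.
    """

    key: str
    value: str
    customer: bool = False
    parsed_value: Any = None

    def source(self) -> str:
        return f"{self.key}={self.value}"


@dataclass
class Annotation:
    """A parsed ``{...}`` annotation block."""

    marker_class: MarkerClass
    marker: str
    entries: list[DictEntry] = field(default_factory=list)
    anchor: int | str | None = None

    def source(self) -> str:
        """The block as written, including the enclosing braces."""
        return "{" + self.marker + serialize_dictionary(self.entries) + "}"

    def entry(self, key: str) -> DictEntry | None:
        for e in self.entries:
            if e.key == key:
                return e
        return None


# --------------------------------------------------------------------------
# seed registries

_DATA = resources.files("curlysmiles") / "data"


def _load_registry(text: str) -> dict[str, str]:
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        marker, _, desc = line.partition("\t")
        table[marker] = desc
    return table


def load_registry_file(path: str | Path) -> dict[str, str]:
    """Load a ``marker<TAB>description`` registry file."""
    return _load_registry(Path(path).read_text())


_KEY_REGISTRY: dict[str, str] | None = None
_MARKER_REGISTRY: dict[str, str] | None = None


def known_keys() -> dict[str, str]:
    global _KEY_REGISTRY
    if _KEY_REGISTRY is None:
        _KEY_REGISTRY = _load_registry((_DATA / "dict_keys.tsv").read_text())
    return _KEY_REGISTRY


def known_markers() -> dict[str, str]:
    """Seed SSAM/MIAM marker registry (extensible; unknowns only warn)."""
    global _MARKER_REGISTRY
    if _MARKER_REGISTRY is None:
        _MARKER_REGISTRY = _load_registry((_DATA / "markers.tsv").read_text())
    return _MARKER_REGISTRY


def extend_registries(keys: dict[str, str] | None = None,
                      markers: dict[str, str] | None = None) -> None:
    """Merge extra entries into the in-memory registries (CLI override)."""
    if keys:
        known_keys().update(keys)
    if markers:
        known_markers().update(markers)


# --------------------------------------------------------------------------
# parsing

def classify_marker(block: str, pos: int = 0) -> tuple[MarkerClass, str, str]:
    """Split an annotation block into (class, marker, dictionary remainder).

    Single-character blocks are resolved first (stereodescriptor or unit
    boundary); anything longer must present a two-character marker.  This
    length-first precedence is what disambiguates the unit boundary ``-``
    from GEAM markers like ``-R`` or ``-|``.
    """
    if not block:
        raise AnnotationError("empty annotation block", pos=pos)
    if len(block) == 1:
        if block in STEREO_LETTERS:
            return MarkerClass.STEREO, block, ""
        if block in BOND_SYMBOLS:
            return MarkerClass.UNIT, block, ""
        raise AnnotationError(
            f"single-character annotation {block!r} is neither a "
            "stereodescriptor nor a boundary bond symbol", pos=pos
        )
    marker, rest = block[:2], block[2:]
    a, b = marker
    if a in BOND_SYMBOLS or a == ".":
        if (b == "Y" and a in BOND_SYMBOLS) or \
           (b in "RX" and a == "-") or \
           (b == "|" and a in "-~."):
            return MarkerClass.GEAM, marker, rest
        raise AnnotationError(
            f"unknown group-environment marker {marker!r}", pos=pos
        )
    if a == "!":
        if b in "apmrHI":
            return MarkerClass.MDAM, marker, rest
        raise AnnotationError(
            f"unknown molecular-detail marker {marker!r}", pos=pos
        )
    if a == "+":
        if b in "RXYLnr":
            return MarkerClass.OPAM, marker, rest
        raise AnnotationError(
            f"unknown operational marker {marker!r}", pos=pos
        )
    if a.isalpha() and b.isalpha():
        cls = MarkerClass.SSAM if (a.islower() and b.islower()) \
            else MarkerClass.MIAM
        if marker not in known_markers():
            warnings.warn(
                f"marker {marker!r} not in the seed registry",
                UnknownMarkerWarning, stacklevel=3,
            )
        return cls, marker, rest
    raise AnnotationError(f"unknown annotation marker shape {block[:2]!r}",
                          pos=pos)


def parse_annotation(block: str, context: str = "end",
                     pos: int = 0) -> Annotation:
    """Parse the text inside one ``{}`` pair into an :class:`Annotation`.

    ``context`` states where the block occurred: ``"atom"`` (directly after
    an atomic node, mid-component), ``"component"`` (component end, after
    a component-anchored annotation has already been seen), or ``"end"``
    (component end, either anchoring still possible).
    """
    cls, marker, rest = classify_marker(block, pos=pos)
    if context == "atom" and cls not in ATOM_CLASSES:
        raise AnnotationError(
            f"{cls.name} annotation {marker!r} is component-anchored and "
            "cannot follow an interior atomic node", pos=pos
        )
    if context == "component" and cls in ATOM_CLASSES:
        raise AnnotationError(
            f"{cls.name} annotation {marker!r} is atom-anchored and cannot "
            "occur in component position", pos=pos
        )
    if cls in (MarkerClass.STEREO, MarkerClass.UNIT) and rest:
        raise AnnotationError(
            f"stereodescriptor/boundary annotation {marker!r} takes no "
            "dictionary", pos=pos
        )
    entries = parse_dictionary(rest, pos=pos + 2) if rest else []
    ann = Annotation(marker_class=cls, marker=marker, entries=entries)
    if cls not in ATOM_CLASSES:
        ann.anchor = COMPONENT
    return ann


def parse_dictionary(text: str, pos: int = 0) -> list[DictEntry]:
    """Parse a ``k1=v1;k2=v2;...`` dictionary remainder.

    Splits on ``;`` only at curly-brace depth 0 so values holding complete
    sub-notations survive intact; each entry splits at its first ``=``.
    """
    if not text:
        return []
    entries: list[DictEntry] = []
    seen: set[str] = set()
    depth = 0
    start = 0
    pieces: list[tuple[str, int]] = []
    for i, ch in enumerate(text):
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
        elif ch == ";" and depth == 0:
            pieces.append((text[start:i], start))
            start = i + 1
    pieces.append((text[start:], start))
    for raw, off in pieces:
        key, eq, value = raw.partition("=")
        if not eq:
            raise DictionaryError(f"entry {raw!r} lacks '='", pos=pos + off)
        if not key:
            raise DictionaryError("empty dictionary key", pos=pos + off)
        if not _KEY_RE.match(key):
            raise DictionaryError(f"malformed key {key!r}", pos=pos + off)
        if key in seen:
            raise DictionaryError(f"duplicate key {key!r}", pos=pos + off)
        seen.add(key)
        customer = key.startswith("$")
        if not customer and key not in known_keys():
            warnings.warn(f"dictionary key {key!r} not in the seed registry",
                          UnknownKeyWarning, stacklevel=3)
        entries.append(DictEntry(key=key, value=value, customer=customer,
                                 parsed_value=_parse_value(key, value)))
    return entries


def _parse_value(key: str, value: str):
    if key == "c":
        # ligand values are complete notations; parse recursively
        from .notation import parse as parse_notation
        return parse_notation(value)
    if _INT_RE.match(value):
        return int(value)
    m = _RANGE_RE.match(value)
    if m:
        return (int(m.group(1)), int(m.group(2)))
    if value == "+":
        return +1
    if value == "-":
        return -1
    return None


def serialize_dictionary(entries: list[DictEntry]) -> str:
    """Rejoin entries as written (byte-identical to the parsed source)."""
    return ";".join(e.source() for e in entries)


def resolve_relative_pointer(ann: Annotation,
                             graph: "MolecularGraph") -> int:
    """Resolve an ``i=`` relative node pointer to an atom index.

    The signed offset counts atomic nodes in appearance order (negative =
    toward earlier atoms) from the annotation's anchor atom.  The referenced
    node must carry an annotation with the same group-environment marker
    (e.g. the ``-|`` annotation holding the surface ``sfn`` description).
    """
    entry = ann.entry("i")
    if entry is None or not isinstance(entry.parsed_value, int):
        raise PointerError("annotation has no integer 'i' entry")
    offset = entry.parsed_value
    if offset == 0:
        raise PointerError("relative pointer offset must be nonzero")
    if not isinstance(ann.anchor, int):
        raise PointerError("pointer annotation is not atom-anchored")
    target = ann.anchor + offset
    if not 0 <= target < len(graph.atoms):
        raise PointerError(
            f"pointer offset {offset:+d} from node {ann.anchor} falls "
            "outside the graph"
        )
    for other in graph.atoms[target].annotations:
        if other.marker == ann.marker and other is not ann:
            return target
    raise PointerError(
        f"node {target} carries no {ann.marker!r} annotation to point to"
    )
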