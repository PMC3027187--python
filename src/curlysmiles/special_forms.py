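"""Alias components and composite notations.

An alias is a curly-braced short name standing for a full component
notation (e.g. ``{bmim(1+)}`` for the 1-butyl-3-methylimidazolium cation).
Predefined aliases resolve against a bundled seed table; customer-defined
aliases carry a leading ``$`` and require a user-supplied look-up table.

A composite notation ``{/c1/c2/.../cn}`` encodes a material whose
constituents are in contact through common interfaces (mesoscale phases,
e.g. a polymer on an oxide).  Each constituent is an SFN (``{*...}``) or an
annotated SMILES component; a composite is always the entire notation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import AliasError, CompositeArityError, NotationError
from .lexer import Form, RawComponent, check_balanced, split_components
from .sfn import SFNComposition, parse_sfn, serialize_sfn
from .smiles_graph import MolecularGraph, parse_plain_smiles, serialize_graph

_ALIAS_RE = re.compile(r"^[A-Za-z$][A-Za-z0-9\-_+()]*$")
_CHARGE_SUFFIX_RE = re.compile(r"\((\d+)([+-])\)$")


@dataclass
class AliasRef:
    """A parsed alias component (name without the enclosing braces)."""

    name: str
    customer: bool = False

    @property
    def declared_charge(self) -> int:
        """Formal charge recoverable from a terminal ``(n+)``/``(n-)`` in
        the name, 0 if absent."""
        m = _CHARGE_SUFFIX_RE.search(self.name)
        if not m:
            return 0
        n = int(m.group(1))
        return n if m.group(2) == "+" else -n

    def source(self) -> str:
        return "{" + self.name + "}"


class Scope(enum.Enum):
    PREDEFINED = "predefined"
    CUSTOMER = "customer"


@dataclass
class AliasTable:
    """A name -> replacement-notation map with a lookup scope."""

    entries: dict[str, str] = field(default_factory=dict)
    scope: Scope = Scope.CUSTOMER


_PREDEFINED: AliasTable | None = None


def predefined_table() -> AliasTable:
    """The bundled seed table of predefined aliases (ionic-liquid ions)."""
    global _PREDEFINED
    if _PREDEFINED is None:
        text = (resources.files("curlysmiles") / "data" / "aliases.tsv"
                ).read_text()
        entries: dict[str, str] = {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            name, _, repl = line.partition("\t")
            entries[name] = repl
        _PREDEFINED = AliasTable(entries=entries, scope=Scope.PREDEFINED)
    return _PREDEFINED


def parse_alias(text: str, pos: int = 0) -> AliasRef:
    """Parse an alias-form component interior (the text between braces)."""
    if not _ALIAS_RE.match(text):
        bad = next((i for i, ch in enumerate(text)
                    if not re.match(r"[A-Za-z0-9\-_+()$]", ch)), 0)
        raise AliasError(f"invalid alias name {text!r}", pos=pos + bad)
    return AliasRef(name=text, customer=text.startswith("$"))


def resolve_alias(ref: AliasRef,
                  tables: list[AliasTable] | None = None) -> RawComponent:
    """Resolve an alias to its replacement component, transitively.

    ``tables`` are searched in order (customer tables are conventionally
    listed first) with the bundled predefined table appended.  Replacement
    notations that are themselves aliases are resolved recursively; a
    visiting set bounds the recursion and turns cycles into errors.
    """
    search = list(tables or [])
    if not any(t.scope is Scope.PREDEFINED for t in search):
        search.append(predefined_table())
    seen: set[str] = set()
    current = ref
    while True:
        if current.name in seen:
            raise AliasError(f"alias cycle through {current.name!r}")
        seen.add(current.name)
        if current.customer and not any(
                t.scope is Scope.CUSTOMER for t in search):
            raise AliasError(
                f"customer-defined alias {current.name!r} requires a "
                "customer look-up table")
        replacement = None
        for table in search:
            if current.customer and table.scope is not Scope.CUSTOMER:
                continue
            if current.name in table.entries:
                replacement = table.entries[current.name]
                break
        if replacement is None:
            raise AliasError(f"unknown alias {current.name!r}")
        comps = split_components(replacement)
        if len(comps) != 1:
            raise AliasError(
                f"replacement for {current.name!r} is not a single component")
        rc = comps[0]
        if rc.form is Form.ALIAS_FORM:
            current = parse_alias(rc.text[1:-1])
            continue
        return rc


@dataclass
class CompositeConstituent:
    """One interface-connected constituent of a composite."""

    text: str
    body: SFNComposition | MolecularGraph

    def source(self) -> str:
        return self.text


@dataclass
class CompositeNotation:
    """An ordered (interface order is meaningful) list of constituents."""

    constituents: list[CompositeConstituent] = field(default_factory=list)

    def source(self) -> str:
        return "{" + "".join("/" + c.source() for c in self.constituents) + "}"


def parse_composite(text: str, pos: int = 0) -> CompositeNotation:
    """Parse a composite interior (the ``/c1/c2/...`` between the braces).

    Slashes split only at curly-brace depth 0, so annotation dictionaries
    inside constituents stay intact.
    """
    if not text.startswith("/"):
        raise CompositeArityError("composite interior must start with '/'",
                                  pos=pos)
    check_balanced(text, pos)
    pieces: list[tuple[str, int]] = []
    depth = 0
    start = 1
    for i, ch in enumerate(text):
        if ch in "{[(":
            depth += 1
        elif ch in "}])":
            depth -= 1
        elif ch == "/" and depth == 0 and i > 0:
            pieces.append((text[start:i], start))
            start = i + 1
    pieces.append((text[start:], start))
    if len(pieces) < 2:
        raise CompositeArityError(
            "a composite needs at least two constituents", pos=pos)
    out = CompositeNotation()
    for raw, off in pieces:
        if not raw:
            raise CompositeArityError("empty constituent", pos=pos + off)
        if raw.startswith("{*") and raw.endswith("}"):
            body = parse_sfn(raw[2:-1], pos=pos + off + 2)
        elif raw.startswith("{"):
            raise NotationError(
                "a constituent must be an SFN or a SMILES component",
                pos=pos + off)
        else:
            body = parse_plain_smiles(raw, pos=pos + off)
        out.constituents.append(CompositeConstituent(text=raw, body=body))
    return out


def load_alias_table(path: str | Path,
                     scope: Scope = Scope.CUSTOMER) -> AliasTable:
    """Load a ``alias<TAB>replacement-notation`` file.

    ``#`` lines are comments; blank lines are skipped; a duplicate alias
    within one file, a malformed line, an invalid alias name, or a
    replacement that does not lex as exactly one component are errors.
    """
    table = AliasTable(scope=scope)
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise AliasError(f"{path}:{ln}: expected alias<TAB>replacement")
        name, repl = fields
        if not _ALIAS_RE.match(name):
            raise AliasError(f"{path}:{ln}: invalid alias name {name!r}")
        if name in table.entries:
            raise AliasError(f"{path}:{ln}: duplicate alias {name!r}")
        try:
            comps = split_components(repl)
        except NotationError as exc:
            raise AliasError(
                f"{path}:{ln}: replacement does not lex: {exc}") from exc
        if len(comps) != 1:
            raise AliasError(
                f"{path}:{ln}: replacement must be a single component")
        table.entries[name] = repl
    return table
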