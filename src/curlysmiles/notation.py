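"""Top-level notation parsing: components of every form, in source order.

``parse`` lexes a notation into components, dispatches each to the parser
for its form (SMILES graph, stoichiometric formula, alias, composite) and
returns a :class:`ParsedNotation` whose serialization reproduces the source
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .lexer import Form, RawComponent, split_components
from .sfn import SFNComposition, parse_sfn, serialize_sfn
from .smiles_graph import MolecularGraph, parse_plain_smiles, serialize_graph
from .special_forms import (
    AliasRef,
    AliasTable,
    CompositeNotation,
    parse_alias,
    parse_composite,
    resolve_alias,
)

ComponentBody = Union[MolecularGraph, SFNComposition, AliasRef,
                      CompositeNotation]


@dataclass
class ParsedComponent:
    """One parsed component plus its lexical envelope (form, multiplier)."""

    raw: RawComponent
    body: ComponentBody

    @property
    def form(self) -> Form:
        return self.raw.form

    @property
    def multiplier(self) -> int:
        return self.raw.multiplier

    def serialize_body(self) -> str:
        body = self.body
        if isinstance(body, MolecularGraph):
            return serialize_graph(body)
        if isinstance(body, SFNComposition):
            return "{*" + serialize_sfn(body) + "}"
        if isinstance(body, AliasRef):
            return body.source()
        return body.source()

    def source(self) -> str:
        text = self.serialize_body()
        if self.multiplier > 1:
            text += f"{{{self.multiplier}}}"
        return text


@dataclass
class ParsedNotation:
    """Ordered parsed components representing a full notation."""

    components: list[ParsedComponent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, i) -> ParsedComponent:
        return self.components[i]


def parse_component(rc: RawComponent) -> ParsedComponent:
    """Parse one lexed component according to its form."""
    if rc.form is Form.SMILES_FORM:
        body: ComponentBody = parse_plain_smiles(rc.text, pos=rc.offset)
    elif rc.form is Form.SFN_FORM:
        body = parse_sfn(rc.text[2:-1], pos=rc.offset + 2)
    elif rc.form is Form.ALIAS_FORM:
        body = parse_alias(rc.text[1:-1], pos=rc.offset + 1)
    else:
        body = parse_composite(rc.text[1:-1], pos=rc.offset + 1)
    return ParsedComponent(raw=rc, body=body)


def parse(notation: str) -> ParsedNotation:
    """Parse a complete notation string."""
    return ParsedNotation(
        components=[parse_component(rc) for rc in split_components(notation)]
    )


def serialize(pn: ParsedNotation) -> str:
    """Serialize a parsed notation; a fixed point of ``parse``."""
    return ".".join(pc.source() for pc in pn.components)


def resolve_aliases(pn: ParsedNotation,
                    tables: list[AliasTable] | None = None) -> ParsedNotation:
    """Replace every alias component by its parsed replacement notation."""
    out = ParsedNotation()
    for pc in pn.components:
        if isinstance(pc.body, AliasRef):
            rc = resolve_alias(pc.body, tables)
            rc.multiplier = max(rc.multiplier, pc.multiplier)
            out.components.append(parse_component(rc))
        else:
            out.components.append(pc)
    return out
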