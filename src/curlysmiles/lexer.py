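"""Brace- and bracket-aware component lexing.

A notation is a string of dot-separated component notations.  Dots inside
curly-brace annotations, square-bracket atom codes, branch parentheses, or
(recursively) annotation dictionary values never split, so splitting happens
only at nesting depth 0 of ``{}``, ``[]`` and ``()`` jointly.  A trailing
``{n}`` with integer n >= 2 is a multiplier and is detached from the
component text; ``{1}`` and ``{0}`` are errors rather than no-ops because a
multiplier is by definition greater than one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import (
    CompositeArityError,
    EmptyComponentError,
    MalformedSpecialFormError,
    MultiplierError,
    NotationError,
    UnbalancedBracesError,
    WhitespaceError,
)

_OPEN = {"{": "}", "[": "]", "(": ")"}
_CLOSE = {v: k for k, v in _OPEN.items()}


class Form(enum.Enum):
    """Form class of a top-level component."""

    SMILES_FORM = "smiles"
    ALIAS_FORM = "alias"
    SFN_FORM = "sfn"
    COMPOSITE_FORM = "composite"


@dataclass
class RawComponent:
    """One dot-separated top-level component.

    ``text`` is the component notation without its multiplier block;
    ``multiplier`` defaults to 1 and is >= 2 whenever a ``{n}`` block was
    present in the source.  ``offset`` is the component's start position in
    the original notation, used for diagnostics.
    """

    text: str
    form: Form = Form.SMILES_FORM
    multiplier: int = 1
    offset: int = 0

    def source(self) -> str:
        """Reassemble the component as written (text plus multiplier block)."""
        if self.multiplier > 1:
            return f"{self.text}{{{self.multiplier}}}"
        return self.text


def check_balanced(text: str, base: int = 0) -> None:
    """Raise if ``{}``, ``[]`` or ``()`` do not balance in ``text``."""
    stack: list[tuple[str, int]] = []
    for i, ch in enumerate(text):
        if ch in _OPEN:
            stack.append((ch, i))
        elif ch in _CLOSE:
            if not stack or stack[-1][0] != _CLOSE[ch]:
                raise UnbalancedBracesError(
                    f"unmatched {ch!r}", pos=base + i
                )
            stack.pop()
    if stack:
        ch, i = stack[-1]
        raise UnbalancedBracesError(f"unclosed {ch!r}", pos=base + i)


def split_components(notation: str) -> list[RawComponent]:
    """Split a notation on top-level dots into classified components.

    Returns components in source order with multipliers detached.  A
    composite component must be the entire notation (unary rule).
    """
    stripped = notation.strip()
    if not stripped:
        raise EmptyComponentError("empty notation", pos=0)
    base = notation.index(stripped[0])
    if any(ch.isspace() for ch in stripped):
        raise WhitespaceError(
            "internal whitespace", pos=base + next(
                i for i, ch in enumerate(stripped) if ch.isspace()
            )
        )
    if not stripped.isascii():
        bad = next(i for i, ch in enumerate(stripped) if not ch.isascii())
        raise NotationError("non-ASCII character", pos=base + bad)
    check_balanced(stripped, base)

    pieces: list[tuple[str, int]] = []
    depth = 0
    start = 0
    for i, ch in enumerate(stripped):
        if ch in _OPEN:
            depth += 1
        elif ch in _CLOSE:
            depth -= 1
        elif ch == "." and depth == 0:
            pieces.append((stripped[start:i], start))
            start = i + 1
    pieces.append((stripped[start:], start))

    components = []
    for text, off in pieces:
        if not text:
            raise EmptyComponentError("empty component", pos=base + off)
        text, mult = _detach_multiplier(text, base + off)
        rc = RawComponent(text=text, multiplier=mult, offset=base + off)
        rc.form = classify_component(rc)
        components.append(rc)

    for rc in components:
        if rc.form is Form.COMPOSITE_FORM and (
            len(components) > 1 or rc.multiplier > 1
        ):
            raise CompositeArityError(
                "a composite notation must be the entire (unary) notation",
                pos=rc.offset,
            )
    return components


def _detach_multiplier(text: str, base: int) -> tuple[str, int]:
    """Detach a trailing ``{digits}`` multiplier block, validating n >= 2."""
    if not text.endswith("}"):
        return text, 1
    i = text.rfind("{")
    inner = text[i + 1 : -1]
    if not inner.isdigit():
        return text, 1
    # a leading all-digit brace block is the whole component, not a multiplier
    if i == 0:
        raise MalformedSpecialFormError(
            "component is a bare multiplier block", pos=base
        )
    n = int(inner)
    if n < 2:
        raise MultiplierError(
            f"multiplier {{{inner}}} must be an integer greater than one",
            pos=base + i,
        )
    return text[:i], n


def classify_component(rc: RawComponent) -> Form:
    """Classify a component's form from its leading characters.

    Special-format components begin with ``{``: ``{*`` opens a
    stoichiometric formula, ``{/`` a composite, and ``{`` followed by a
    letter or ``$`` an alias.  Everything else is (annotated) SMILES.
    """
    text = rc.text
    if not text.startswith("{"):
        return Form.SMILES_FORM
    if len(text) < 3 or not text.endswith("}"):
        raise MalformedSpecialFormError("truncated special form", pos=rc.offset)
    head = text[1]
    if head == "*":
        return Form.SFN_FORM
    if head == "/":
        return Form.COMPOSITE_FORM
    if head.isalpha() or head == "$":
        return Form.ALIAS_FORM
    raise MalformedSpecialFormError(
        f"'{{' followed by {head!r} opens no special form", pos=rc.offset + 1
    )


def rejoin(components: list[RawComponent]) -> str:
    """Inverse of :func:`split_components` (lossless lexing)."""
    return ".".join(rc.source() for rc in components)
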