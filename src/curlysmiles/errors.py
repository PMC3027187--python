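"""Exception hierarchy for notation parsing and validation.

Every error derives from :class:`NotationError` and may carry the 0-based
character offset into the original notation at which the rule was violated;
the offset is embedded in the message so diagnostics stay useful when the
exception is stringified by batch tooling.
"""

from __future__ import annotations


class NotationError(ValueError):
    """Base class for all notation syntax and validation errors."""

    def __init__(self, message: str, pos: int | None = None):
        self.pos = pos
        if pos is not None:
            message = f"{message} (at offset {pos})"
        super().__init__(message)


class UnbalancedBracesError(NotationError):
    """Curly braces, square brackets or parentheses do not balance."""


class EmptyComponentError(NotationError):
    """A dot-separated component is empty (leading/trailing/double dot)."""


class WhitespaceError(NotationError):
    """Internal whitespace: notations are single words."""


class MultiplierError(NotationError):
    """A trailing ``{n}`` multiplier with n < 2 (multipliers must exceed one)."""


class CompositeArityError(NotationError):
    """A composite notation that is not the entire (unary) notation, or has
    fewer than two constituents."""


class MalformedSpecialFormError(NotationError):
    """``{`` followed by a character that opens no known special form."""


class StereoGlyphError(NotationError):
    """``@``, ``/`` or ``\\`` in SMILES code: stereochemistry is expressed via
    stereodescriptor annotations, not glyphs."""


class BondEndpointError(NotationError):
    """A ``~`` or ``$`` bond whose endpoint is not square-bracket encoded, or a
    bare (non-bracketed) atomic wildcard."""


class UnknownElementError(NotationError):
    """Token does not match any IUPAC element symbol."""


class RingClosureError(NotationError):
    """Ring-bond label opened but never closed, closed twice, or closed with
    conflicting bond symbols."""


class BranchError(NotationError):
    """Unbalanced or empty branch parentheses."""


class SqcError(NotationError):
    """Malformed square-bracket atomic code."""


class AnnotationError(NotationError):
    """Unknown annotation marker shape, or an annotation anchored at an
    illegal position."""


class DictionaryError(NotationError):
    """Malformed annotation dictionary (entry without '=', empty or duplicate
    key)."""


class PointerError(NotationError):
    """A relative node pointer (``i=`` entry) that resolves out of range or to
    a node lacking the referenced annotation."""


class SfnError(NotationError):
    """Malformed stoichiometric formula notation."""


class ChargePlacementError(SfnError):
    """SFN charge suffix occurring anywhere but at the very end."""


class AliasError(NotationError):
    """Unknown alias, alias cycle, bad alias alphabet, or a customer alias
    looked up without a customer table."""


class StrictStripError(NotationError):
    """Annotation stripping refused: removing the annotations would change the
    chemical identity of the notation."""


class UnknownKeyWarning(UserWarning):
    """Dictionary key not present in the seed key registry."""


class UnknownMarkerWarning(UserWarning):
    """SSAM/MIAM marker not present in the seed marker registry."""


class AmbiguousBondWarning(UserWarning):
    """``&`` used as a graph bond symbol; stored opaquely."""
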