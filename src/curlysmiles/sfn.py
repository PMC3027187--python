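"""Stoichiometric formula notations (SFN).

An SFN encodes a material by atomic composition rather than connectivity:
element symbols each followed by an optional stoichiometric integer, with
``^``-prefixed isotope labels, arbitrarily nested parenthesized groups whose
trailing integer multiplies everything inside, and an optional terminal
``(n+)``/``(n-)`` net-charge suffix.  The same symbol may repeat and symbols
may occur in any order, so equality of two formulas is decided on the
flattened element -> count map plus charge, not on the written tree.

As a component an SFN is wrapped as ``{*...}``; the bare grammar also
appears inside composite constituents and as annotation dictionary values
(e.g. ``sfn=SiO2``).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .elements import is_element
from .errors import ChargePlacementError, SfnError, UnknownElementError

_CHARGE_RE = re.compile(r"^\((\d+)([+-])\)")


@dataclass
class SFNItem:
    """One element entry: optional isotope label, symbol, count."""

    symbol: str
    count: int = 1
    isotope: int | None = None
    explicit_count: bool = False

    @property
    def species(self) -> str:
        """Flattening key; isotope-labeled species stay distinct (^13C != C)."""
        return f"^{self.isotope}{self.symbol}" if self.isotope else self.symbol

    def source(self) -> str:
        iso = f"^{self.isotope}" if self.isotope else ""
        cnt = str(self.count) if (self.explicit_count or self.count > 1) else ""
        return f"{iso}{self.symbol}{cnt}"


@dataclass
class SFNGroup:
    """A parenthesized group: ordered items, each an SFNItem or a nested
    group, with a trailing count that multiplies through."""

    items: list = field(default_factory=list)
    count: int = 1
    explicit_count: bool = False

    def source(self, root: bool = False) -> str:
        inner = "".join(
            it.source() if isinstance(it, SFNItem) else it.source()
            for it in self.items
        )
        if root:
            return inner
        cnt = str(self.count) if (self.explicit_count or self.count > 1) else ""
        return f"({inner}){cnt}"

    def flatten(self) -> Counter:
        total: Counter = Counter()
        for it in self.items:
            if isinstance(it, SFNItem):
                total[it.species] += it.count
            else:
                sub = it.flatten()
                for k, v in sub.items():
                    total[k] += v
        for k in total:
            total[k] *= self.count
        return total


@dataclass
class SFNComposition:
    """Parsed SFN: the source tree, its flattened composition, net charge."""

    root: SFNGroup
    flattened: dict[str, int]
    charge: int = 0

    def total_atoms(self) -> int:
        return sum(self.flattened.values())


def parse_sfn(text: str, pos: int = 0) -> SFNComposition:
    """Parse the bare SFN grammar (content between ``{*`` and ``}``).

    Element tokenization is greedy two-letter-first against the bundled
    IUPAC table, so ``Co`` is cobalt, never carbon + oxygen.
    """
    if not text:
        raise SfnError("empty stoichiometric formula", pos=pos)
    root, i, charge = _parse_group(text, 0, pos, depth=0)
    if i != len(text):
        raise SfnError(f"unexpected {text[i]!r} in formula", pos=pos + i)
    flattened = dict(root.flatten())
    return SFNComposition(root=root, flattened=flattened, charge=charge)


def _parse_group(text: str, i: int, pos: int,
                 depth: int) -> tuple[SFNGroup, int, int]:
    group = SFNGroup()
    charge = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == ")":
            if depth == 0:
                raise SfnError("unmatched ')'", pos=pos + i)
            return group, i, charge
        if ch == "(":
            m = _CHARGE_RE.match(text[i:])
            if m:
                if depth != 0:
                    raise ChargePlacementError(
                        "charge suffix inside a nested group", pos=pos + i)
                if i + m.end() != n:
                    raise ChargePlacementError(
                        "charge suffix must terminate the formula",
                        pos=pos + i)
                val = int(m.group(1))
                if val < 1:
                    raise SfnError("charge magnitude must be >= 1",
                                   pos=pos + i)
                charge = val if m.group(2) == "+" else -val
                return group, n, charge
            sub, j, _ = _parse_group(text, i + 1, pos, depth + 1)
            if j >= n or text[j] != ")":
                raise SfnError("unclosed '('", pos=pos + i)
            if not sub.items:
                raise SfnError("empty group", pos=pos + i)
            j += 1
            cnt, j, explicit = _read_count(text, j, pos)
            sub.count = cnt
            sub.explicit_count = explicit
            group.items.append(sub)
            i = j
            continue
        isotope = None
        if ch == "^":
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            if j == i + 1:
                raise SfnError("dangling '^' isotope marker", pos=pos + i)
            isotope = int(text[i + 1 : j])
            i = j
            if i >= n or not text[i].isupper():
                raise SfnError("isotope label must precede an element symbol",
                               pos=pos + i)
            ch = text[i]
        if ch.isupper():
            sym = None
            two = text[i : i + 2]
            if len(two) == 2 and two[1].islower() and is_element(two):
                sym = two
            elif is_element(ch):
                sym = ch
            if sym is None:
                raise UnknownElementError(
                    f"unknown element token at {text[i:i+2]!r}", pos=pos + i)
            i += len(sym)
            cnt, i, explicit = _read_count(text, i, pos)
            group.items.append(SFNItem(symbol=sym, count=cnt, isotope=isotope,
                                       explicit_count=explicit))
            continue
        raise SfnError(f"unexpected {ch!r} in formula", pos=pos + i)
    return group, i, charge


def _read_count(text: str, i: int, pos: int) -> tuple[int, int, bool]:
    j = i
    while j < len(text) and text[j].isdigit():
        j += 1
    if j == i:
        return 1, i, False
    cnt = int(text[i:j])
    if cnt == 0:
        raise SfnError("zero stoichiometric count", pos=pos + i)
    return cnt, j, True


def serialize_sfn(comp: SFNComposition) -> str:
    """Emit the formula tree in source order (round-trips byte-identically)."""
    out = comp.root.source(root=True)
    if comp.charge:
        sign = "+" if comp.charge > 0 else "-"
        out += f"({abs(comp.charge)}{sign})"
    return out


def compare_compositions(a: SFNComposition, b: SFNComposition) -> bool:
    """Order- and grouping-insensitive equality: flattened maps and charges."""
    return a.flattened == b.flattened and a.charge == b.charge


def composition_from_counts(counts: dict[str, int],
                            charge: int = 0) -> SFNComposition:
    """Build a composition directly from an element -> count map."""
    items = []
    for key, count in counts.items():
        m = re.match(r"^\^(\d+)([A-Za-z]+)$", key)
        if m:
            items.append(SFNItem(symbol=m.group(2), count=count,
                                 isotope=int(m.group(1))))
        else:
            items.append(SFNItem(symbol=key, count=count))
    group = SFNGroup(items=items)
    flattened = dict(group.flatten())
    return SFNComposition(root=group, flattened=flattened, charge=charge)
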