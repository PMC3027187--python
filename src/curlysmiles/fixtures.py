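"""Deterministic generator of valid and deliberately broken notations.

``generate_notation(seed, profile)`` emits a reproducible notation together
with a ground-truth record filled in *while the string is being built*
(component count, multipliers, atom/bond counts, planted annotations and
pointer targets, flattened formula maps), so property tests can compare the
parser's output against bookkeeping that never touched the parser.

``mutate_invalid`` applies exactly one corruption to a valid notation and
names the error class the parser must raise for it.

Generation limits are deliberately small (<= 12 atoms per component, <= 5
components, formula nesting <= 3) so brute-force oracles stay trivial; the
generator makes no attempt at chemical sensibility.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from . import errors

PROFILES = ("plain", "annotated", "sfn", "composite", "mixed")

_BARE_ATOMS = ["C", "C", "C", "N", "O", "P", "S", "Cl", "Br"]
_SQC_ATOMS = ["[Si]", "[Na+]", "[O-]", "[13C]", "[Fe+2]", "[*H2]", "[SeH]"]
_BONDS = ["", "", "", "", "=", "#"]
_SSAM_MARKERS = ["aq", "cr", "np", "tf"]


@dataclass
class ComponentTruth:
    form: str
    multiplier: int = 1
    atoms: int | None = None
    bonds: int | None = None
    flattened: dict | None = None
    charge: int = 0
    annotations: list = field(default_factory=list)  # (anchor, marker)
    pointers: list = field(default_factory=list)     # (anchor, offset, target)
    constituents: int | None = None


@dataclass
class GroundTruth:
    components: list[ComponentTruth] = field(default_factory=list)

    @property
    def component_count(self) -> int:
        return len(self.components)

    @property
    def total_multiplicity(self) -> int:
        return sum(c.multiplier for c in self.components)


def _rng(seed: int, profile: str) -> random.Random:
    return random.Random(f"{seed}:{profile}")


# --------------------------------------------------------------------------
# SMILES-form components

def _gen_smiles(rng: random.Random, annotated: bool) -> tuple[str,
                                                              ComponentTruth]:
    truth = ComponentTruth(form="smiles")
    n_chain = rng.randint(1, 6)
    parts: list[str] = []
    atom_count = 0
    bond_count = 0
    appearance: list[int] = []  # appearance index of each main-chain atom

    ring = n_chain >= 3 and rng.random() < 0.4
    sqc_pair_at = rng.randint(0, n_chain - 2) if (
        n_chain >= 2 and rng.random() < 0.3) else None

    def emit_atom(forced_sqc: bool = False) -> int:
        nonlocal atom_count
        idx = atom_count
        if forced_sqc or rng.random() < 0.2:
            parts.append(rng.choice(_SQC_ATOMS))
        else:
            parts.append(rng.choice(_BARE_ATOMS))
        atom_count += 1
        return idx

    for i in range(n_chain):
        if i > 0:
            if sqc_pair_at is not None and i == sqc_pair_at + 1:
                parts.append("~")
            else:
                parts.append(rng.choice(_BONDS))
            bond_count += 1
        forced = sqc_pair_at is not None and i in (sqc_pair_at,
                                                   sqc_pair_at + 1)
        idx = emit_atom(forced_sqc=forced)
        appearance.append(idx)
        if ring and i in (0, n_chain - 1):
            parts.append("1")
            if i == n_chain - 1:
                bond_count += 1
        if annotated and rng.random() < 0.3:
            marker = rng.choice(["R", "S", "-", "=Y", "!a", "+X"])
            parts.append("{" + marker + "}")
            truth.annotations.append((idx, marker))
        if rng.random() < 0.25 and i < n_chain - 1:
            # short branch
            blen = rng.randint(1, 2)
            parts.append("(")
            for j in range(blen):
                if j > 0:
                    parts.append(rng.choice(_BONDS))
                emit_atom()
                bond_count += 1
            parts.append(")")

    if annotated and n_chain >= 3 and rng.random() < 0.5:
        # plant a surface annotation plus a relative pointer onto it
        i_pos, j_pos = sorted(rng.sample(range(n_chain), 2))
        target, anchor = appearance[i_pos], appearance[j_pos]
        offset = target - anchor
        parts = _insert_after_atom(parts, target, "{-|sfn=SiO2}")
        parts = _insert_after_atom(parts, anchor, "{-|i=%+d}" % offset)
        truth.annotations.append((target, "-|"))
        truth.annotations.append((anchor, "-|"))
        truth.pointers.append((anchor, offset, target))

    if annotated and rng.random() < 0.4:
        marker = rng.choice(_SSAM_MARKERS)
        parts.append("{" + marker + "}")
        truth.annotations.append(("component", marker))

    truth.atoms = atom_count
    truth.bonds = bond_count
    return "".join(parts), truth


def _insert_after_atom(parts: list[str], atom_idx: int,
                       block: str) -> list[str]:
    """Insert an annotation block right after the atom_idx-th atom token
    (and after any ring digit that follows it)."""
    out: list[str] = []
    seen = -1
    placed = False
    i = 0
    while i < len(parts):
        tok = parts[i]
        out.append(tok)
        if tok in _BARE_ATOMS or tok in _SQC_ATOMS:
            seen += 1
            if seen == atom_idx and not placed:
                # carry over ring digits first
                while i + 1 < len(parts) and parts[i + 1].isdigit():
                    out.append(parts[i + 1])
                    i += 1
                out.append(block)
                placed = True
        i += 1
    return out


# --------------------------------------------------------------------------
# SFN components

_SFN_ELEMENTS = ["C", "O", "Si", "Cr", "Fe", "Na", "Cl", "S", "N", "Al", "Zr"]


def _gen_sfn_group(rng: random.Random, depth: int,
                   flattened: dict, factor: int) -> str:
    n_items = rng.randint(1, 3)
    out = []
    for _ in range(n_items):
        if depth < 3 and rng.random() < 0.3:
            count = rng.randint(1, 4)
            inner = _gen_sfn_group(rng, depth + 1, flattened, factor * count)
            out.append(f"({inner}){count if count > 1 else ''}")
        else:
            sym = rng.choice(_SFN_ELEMENTS)
            species = sym
            if rng.random() < 0.15:
                species = f"^{rng.randint(2, 60)}{sym}"
            count = rng.randint(1, 5)
            out.append(species + (str(count) if count > 1 else ""))
            flattened[species] = flattened.get(species, 0) + count * factor
    return "".join(out)


def _gen_sfn(rng: random.Random) -> tuple[str, ComponentTruth]:
    flattened: dict = {}
    body = _gen_sfn_group(rng, 0, flattened, 1)
    charge = 0
    if rng.random() < 0.3:
        mag = rng.randint(1, 4)
        sign = rng.choice("+-")
        body += f"({mag}{sign})"
        charge = mag if sign == "+" else -mag
    truth = ComponentTruth(form="sfn", flattened=flattened, charge=charge)
    return "{*" + body + "}", truth


# --------------------------------------------------------------------------
# public API

def generate_notation(seed: int, profile: str) -> tuple[str, GroundTruth]:
    """Generate one reproducible notation with ground truth for a profile
    in ``PROFILES``."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    rng = _rng(seed, profile)
    truth = GroundTruth()
    if profile in ("plain", "annotated"):
        text, ct = _gen_smiles(rng, annotated=(profile == "annotated"))
        truth.components.append(ct)
        return text, truth
    if profile == "sfn":
        text, ct = _gen_sfn(rng)
        truth.components.append(ct)
        return text, truth
    if profile == "composite":
        n = rng.randint(2, 4)
        pieces = []
        for _ in range(n):
            if rng.random() < 0.5:
                t, _ct = _gen_sfn(rng)
                pieces.append(t)
            else:
                t, _ct = _gen_smiles(rng, annotated=False)
                pieces.append(t)
        ct = ComponentTruth(form="composite", constituents=n)
        truth.components.append(ct)
        return "{" + "".join("/" + p for p in pieces) + "}", truth
    # mixed
    n = rng.randint(1, 5)
    parts = []
    for _ in range(n):
        kind = rng.choice(["plain", "annotated", "sfn", "alias"])
        if kind == "alias":
            text = rng.choice(["{bmim(1+)}", "{NTf2(1-)}", "{emim(1+)}"])
            ct = ComponentTruth(form="alias")
        elif kind == "sfn":
            text, ct = _gen_sfn(rng)
        else:
            text, ct = _gen_smiles(rng, annotated=(kind == "annotated"))
        if rng.random() < 0.35:
            ct.multiplier = rng.randint(2, 6)
            text += f"{{{ct.multiplier}}}"
        parts.append(text)
        truth.components.append(ct)
    return ".".join(parts), truth


#: mutation name -> error class the parser must raise
MUTATION_ERRORS = {
    "unbalance": errors.UnbalancedBracesError,
    "stereo_glyph": errors.StereoGlyphError,
    "multiplier_one": errors.MultiplierError,
    "nonunary_composite": errors.CompositeArityError,
    "strip_sqc": errors.BondEndpointError,
}

_MULT_RE = re.compile(r"\{(\d+)\}")
_SQC_TILDE_RE = re.compile(r"\[[^\]]+\]~")


def mutate_invalid(notation: str, seed: int) -> tuple[str, type]:
    """Apply one random applicable corruption; return the corrupted string
    and the error class a conforming parser must raise on it."""
    rng = _rng(seed, "mutate")
    options: list[tuple[str, str]] = []

    if "}" in notation:
        i = notation.rindex("}")
        options.append(("unbalance", notation[:i] + notation[i + 1 :]))
    else:
        options.append(("unbalance", notation + "}"))

    # insert '@' after a bare atom letter in a depth-0 SMILES region, where
    # the parser is guaranteed to see it as a stereo glyph
    depth = 0
    for i, ch in enumerate(notation):
        if ch in "{[":
            depth += 1
        elif ch in "}]":
            depth -= 1
        elif depth == 0 and ch.isupper():
            options.append(
                ("stereo_glyph", notation[: i + 1] + "@" + notation[i + 1 :]))
            break

    m = _MULT_RE.search(notation)
    if m:
        options.append(
            ("multiplier_one", notation[: m.start()] + "{1}"
             + notation[m.end() :]))

    if notation.startswith("{/"):
        options.append(("nonunary_composite", "C." + notation))

    m = _SQC_TILDE_RE.search(notation)
    if m:
        options.append(
            ("strip_sqc", notation[: m.start()] + "C~" + notation[m.end() :]))

    name, mutated = rng.choice(options)
    return mutated, MUTATION_ERRORS[name]
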