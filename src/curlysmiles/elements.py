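"""Bundled element symbol table and standard-valence data.

The 118 IUPAC element symbols, used for greedy two-letter-first tokenization
of stoichiometric formulas and for square-bracket atom validation.
"""

from __future__ import annotations

ELEMENTS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

#: Elements writable without square brackets; hydrogens implied by valence.
ORGANIC_SUBSET: frozenset[str] = frozenset(
    ["B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"]
)

#: Symbols that may appear lowercase (aromatic) as bare atoms.
AROMATIC_BARE: frozenset[str] = frozenset(["b", "c", "n", "o", "p", "s"])

#: Bracket symbols additionally accepted in aromatic (lowercase) form.
AROMATIC_BRACKET: frozenset[str] = AROMATIC_BARE | frozenset(["se", "as"])

#: Standard valences used to materialize implicit hydrogen counts on bare
#: organic-subset atoms (smallest valence >= explicit bond-order sum wins).
STANDARD_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}


def is_element(symbol: str) -> bool:
    return symbol in ELEMENTS
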