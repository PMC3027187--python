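import warnings

import pytest

from curlysmiles.errors import UnknownKeyWarning, UnknownMarkerWarning

#: The worked example notations of the language definition: cobalt(II)
#: nitrate hexahydrate (multiplier shorthand), ionic-liquid aliases,
#: stoichiometric formulas, the MEEP/zirconia composite, wildcard bonding,
#: the silica-immobilized imidazolium surface species, the calix[4]arene
#: repeat unit and its europium complex, and the generic grafted-alkyl
#: pattern.
PRINTED_NOTATIONS = [
    "[Co+2].[O-]N(=O)=O{2}.O{6}",
    "{bmim(1+)}.{NTf2(1-)}",
    "{$myCation}.{$myAnion}.{$mySolvate}{4}",
    "{*Cr23C6}",
    "{*Bi5(4+)}",
    "{*Cu3(CO3)2(OH)2}",
    "{*K(AuS(S2))}",
    "{/N{-}=P{+n}(OCCOCCOC)(OCCOCCOC)/{*ZrO2}}",
    "[*H2]=[*]",
    "O{-|sfn=SiO2}[Si](O{-|i=-2})(O)CCCn1ccn{-R}c1{!re=+}",
    "CC(=O)COc1c{-}cc{-R}cc1C{+rn=4}",
    "[Eu+3]{+Lc=CC(=O)COc1c{-}cc{-R}cc1C{+rn=4}}",
    "[*]{+Rn=4-16}{-|}",
]

FIGURE1 = "O{-|sfn=SiO2}[Si](O{-|i=-2})(O)CCCn1ccn{-R}c1{!re=+}"
CALIX_UNIT = "CC(=O)COc1c{-}cc{-R}cc1C{+rn=4}"
EU_COMPLEX = "[Eu+3]{+Lc=CC(=O)COc1c{-}cc{-R}cc1C{+rn=4}}"
MEEP_UNIT = "N{-}=P{+n}(OCCOCCOC)(OCCOCCOC)"
COBALT_NITRATE = "[Co+2].[O-]N(=O)=O{2}.O{6}"
COBALT_NITRATE_EXHAUSTIVE = "[Co+2].[O-]N(=O)=O.[O-]N(=O)=O.O.O.O.O.O.O"


@pytest.fixture(autouse=True)
def _silence_registry_warnings():
    # fuzzed notations legitimately use markers/keys outside the seed
    # registries; the warnings are part of the design, not test noise
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnknownKeyWarning)
        warnings.simplefilter("ignore", UnknownMarkerWarning)
        yield
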