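# curlysmiles

A parser, validator and transformer for **CurlySMILES** notations — a
superset of SMILES for chemistry that plain molecular graphs cannot carry:
surface-attached species, coordination complexes, macromolecules and
macrocycles given as repeat units, non-molecular solids given by
stoichiometry, composites of interface-connected phases, and solutions or
ionic liquids written with aliases.

It is aimed at cheminformatics developers and materials-informatics groups
who need to store, validate, exchange and programmatically rewrite such
notations — for example to index annotated structures in a database, to
expand shorthand into explicit structures, or to match materials by
composition regardless of how the formula was written.

## The notation in brief

A notation is a string of dot-separated components. A component is either
(annotated) SMILES or a special form opening with `{`:

| form | syntax | example | meaning |
|---|---|---|---|
| annotated SMILES | `...{AM k=v;...}...` | `C{-}` | methyl *group* (open bond), distinct from the radical `[CH3]` |
| alias | `{name}` / `{$name}` | `{bmim(1+)}` | short name for a component; `$` = user-defined |
| stoichiometric formula (SFN) | `{*...}` | `{*Cr23C6}` | composition, with nesting `Cu3(CO3)2(OH)2`, isotopes `^13C`, terminal charge `(4+)` |
| composite | `{/c1/c2/...}` | `{/…/{*ZrO2}}` | phases in contact through interfaces |
| multiplier | `component{n}`, n ≥ 2 | `O{6}` | n copies of the component |

Curly-brace annotations anchor to the preceding atom (only ring digits may
intervene) or to the whole component, and are classified by marker:
stereodescriptors (`{R}`, `{Z}`), structural-unit boundaries (`{-}` = open
single bond), group environments (`{-|}` surface attachment, `{-R}` alkyl
substituent), molecular details (`{!r…}` ring charge), operational markers
(`{+rn=4}` repeat a unit four times into a macrocycle, `{+n}` linear chain,
`{+L}` ligand addition), and component-level state/shape terms (`{aq}`).
Dictionary values can hold complete notations, so the language is
recursive; stereo glyphs `@ / \` are rejected in favour of annotations.

## Worked example

The silica-immobilized alkylimidazolium species — an imidazolium cation
tethered through a propyl chain to two surface-bound oxygens — is a single
annotated component:

```sh
$ curlysmiles parse "O{-|sfn=SiO2}[Si](O{-|i=-2})(O)CCCn1ccn{-R}c1{!re=+}"
component 0 [smiles]: 12 atoms, 12 bonds, 4 annotations
```

The 12 atoms are the molecular skeleton; the 4 annotations say the rest:
two `-|` surface attachments (the first names the substrate `sfn=SiO2`, the
second points back at it with the relative node offset `i=-2`), an `-R`
alkyl substituent on the ring nitrogen, and `!r` marking the delocalized
positive ring charge (`e=+`) at the ring-closing atom. Stripping the
annotations leaves the plain connectivity skeleton:

```sh
$ curlysmiles strip "O{-|sfn=SiO2}[Si](O{-|i=-2})(O)CCCn1ccn{-R}c1{!re=+}"
O[Si](O)(O)CCCn1ccnc1
```

Multiplier shorthand expands to the exhaustive notation — cobalt(II)
nitrate hexahydrate:

```sh
$ curlysmiles expand "[Co+2].[O-]N(=O)=O{2}.O{6}"
[Co+2].[O-]N(=O)=O.[O-]N(=O)=O.O.O.O.O.O.O
```

Formulas flatten through arbitrary nesting (azurite), and match
order-insensitively:

```sh
$ curlysmiles formula "{*Cu3(CO3)2(OH)2}"
Cu      3
C       2
O       8
H       2
charge  0
$ curlysmiles match-sfn "{*C6Cr23}" "{*Cr23C6}"
match
```

The same operations are available as a library: `parse`, `serialize`,
`expand_multipliers`, `expand_ring_repeat`/`expand_chain_repeat` (rewrite
`+r`/`+n` repeat units into explicit macrocycles/chains),
`strip_annotations`, `molecular_formula`, `compare_compositions`,
`resolve_aliases`. Parsing preserves the source exactly:
`serialize(parse(s)) == s` byte-for-byte.

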