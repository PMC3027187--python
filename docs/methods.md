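# Methods

This note records how the package reads the notation grammar, the choices
made where the language definition leaves room, and what the test corpus
does and does not establish.

## Lexing model

A notation is split on `.` only at joint nesting depth 0 of `{}`, `[]` and
`()`. Tracking all three bracket kinds together is what lets annotation
dictionary values contain complete sub-notations (the europium-complex
ligand value holds dots, braces and brackets) without ever splitting them.
Leading/trailing whitespace is stripped; internal whitespace is an error —
notations are single words. Input must be ASCII.

A trailing `{digits}` block at depth 0 is a multiplier only if the integer
is ≥ 2; `{1}` and `{0}` are hard errors rather than no-ops, because a
multiplier is defined as an integer greater than one, and silently
accepting `{1}` would make lexing lossy. A composite component must be the
entire notation; we also reject a multiplier on a composite, reading the
unary rule strictly.

Lexing is lossless: rejoining component texts with `.` and re-appending
multipliers reproduces the input byte-for-byte, and this is tested on every
worked example and on the fuzzed corpus.

## SMILES dialect

The graph parser accepts standard SMILES atoms, branches, `%nn` ring
labels, and the bond symbols `- = # $ : ~ &`, with three deviations that
define this dialect:

* `@`, `/` and `\` raise a dedicated stereo-glyph error whose message
  points at stereodescriptor annotations; stereochemistry lives in
  annotations, never in glyphs.
* the wildcard atom must be bracket-encoded (`[*]`), and both endpoints of
  a `~` (unspecified) or `$` (quadruple) bond must be bracket-encoded;
  violations raise at bond construction, including for ring-closure bonds.
* `&` is accepted as a bond symbol but stored opaquely as "ambiguous" with
  a warning: the language lists it among bond symbols for boundary
  descriptors without defining a chemical meaning, and we decline to guess.

Ring-closure bonds whose two ends carry different explicit symbols are
errors; identical or one-sided symbols are fine. Aromatic lowercase is
accepted for b, c, n, o, p, s and bracketed se/as; aromatic flags are
purely syntactic — no aromaticity perception or kekulization is attempted.

Implicit hydrogens on bare organic-subset atoms are not stored but
materialized on demand from a standard-valence table (B 3; C 4; N 3,5;
O 2; P 3,5; S 2,4,6; halogens 1), taking the smallest valence that
accommodates the rounded-up bond-order sum (aromatic bonds count 1.5).
Aromatic atoms are never promoted to a higher valence: a three-connected
aromatic nitrogen is pyrrole-like and carries no hydrogen. This matches
RDKit's counts on the shared plain-SMILES subset, which the tests verify
directly. Annotations that stand for an open or replaced bond (boundary
descriptors, surface attachment, substituent markers) each consume one
valence unit, so the methyl group `C{-}` reports three hydrogens like the
radical it must not be confused with, and a surface-bound oxygen `O{-|…}`
with one graph bond reports zero. Ionic surface interaction (`.|`)
consumes none. Valence violations are not hard errors (warnings-level
philosophy); formula derivation simply floors at zero hydrogens.

## Annotation anchoring

Classification is longest-match with single-character classes first: a
lone `D/E/L/R/S/Z` is a stereodescriptor, a lone bond symbol a unit
boundary; everything else must present a two-character marker (`-R`, `-|`,
`!r`, `+n`, …). This resolves the `-` vs `-R`/`-|` ambiguity by length.
The printed `. |` form is normalized to the contiguous `.|` (typesetting
space). Unknown two-letter markers that are shaped like state/shape or
miscellaneous markers warn rather than fail: those vocabularies are
external, extensible registries, and the package ships small seed files
(`data/markers.tsv`, `data/dict_keys.tsv`) that users can extend via the
`--registries` flag. Keys prefixed with `$` are customer-defined and never
checked.

Anchoring is positional: a block directly after an atom (ring digits may
intervene, in that order — digits first) anchors to that atom if its class
is atom-anchored; state/shape and miscellaneous markers may appear only in
the component-end run of blocks. At the end of a component, atom-anchored
blocks still attach to the final atom, and may be followed by
component-anchored blocks, never the reverse. Multiple annotations on one
atom are allowed and order-preserved.

Relative pointers (`i=` entries, counting atomic nodes signed in
appearance order) are resolved by an explicit operation, not at parse
time: a fragment such as `O{-|i=-2}` is a legal notation on its own even
though its pointer only resolves inside the component it was cut from.
Resolution demands the target node carry an annotation with the same
group-environment marker.

Dictionary values are typed opportunistically: signed integers, `lo-hi`
ranges, charge tokens `+`/`-`, and — for the ligand key `c` — a complete
recursively parsed notation, eagerly at parse time. Everything else stays
a raw string; unknown keys warn. Re-serializing a dictionary reproduces
its source text byte-for-byte.

## Stoichiometric formulas

Element tokenization is greedy two-letter-first against the bundled
118-symbol IUPAC table (`Co` is cobalt, never C+O). Isotope labels bind to
the immediately following single symbol; isotope-labeled species flatten
as distinct keys (`^13C` ≠ `C`). Group counts multiply through all nesting
levels; a charge suffix is legal only at the very end and only at the top
level. Formula equality is decided on the flattened map plus charge, never
on the written tree, and serialization preserves source order and explicit
`1` counts so parse→serialize is byte-identical.

## Repeat-unit expansion

A `+r` unit with boundary descriptor `b` and count k expands so that the
`+r` atom of copy j bonds to the boundary atom of copy j+1, the last copy
closing onto the first — k join bonds forming one macrocycle. The join
order comes from the boundary descriptor; the boundary and `+r`
annotations are consumed, all other annotations are copied per unit (the
calixarene's `-R` substituent recurs on every ring unit, which matches the
chemistry even though the text never says so explicitly). `+n` chains join
the same way but leave both terminal bonds dangling, marked with boundary
annotations; an open-ended `+n` (no `n=` entry) requires the caller to
supply the count. Join bonds are appended after all unit bonds, so the
final k bonds of the result are the joins — the property tests rely on
this to verify that join removal leaves k isomorphic unit copies.

`+R`/`+X`/`+Y` substitution markers and generic `=Y` environments are
matching semantics, not rewrites: they are stored as pattern annotations
(with their ranges kept symbolic, e.g. `n=4-16`) rather than expanded into
molecule enumerations.

## Serialization

Parsing records an emission plan — atoms, literal characters and
annotation blocks in source order — so serializing a parsed graph replays
the source byte-for-byte (bracket-atom interiors are kept verbatim, which
preserves idiosyncratic but legal spellings such as `++` charges).
Constructed graphs (expansion outputs) have no plan and use a generic
depth-first writer: spanning-tree DFS in atom-index order, non-tree edges
as freshly numbered ring closures, explicit bond symbols only where the
default would differ. Its output is guaranteed to re-parse to an
isomorphic graph, not to any particular spelling.

## Aliases

Lookup keys include the charge suffix (`bmim(1+)`, not `bmim`), since the
alias alphabet admits parentheses and plus signs and the charge is what
distinguishes ions. Customer names keep their `$` in the key, so the
predefined and customer namespaces cannot collide. Resolution is
transitive with a visiting set, so cycles of any length are detected. The
shipped predefined table is a deliberately small seed (five ionic-liquid
ions) standing in for an external registry; a miss after searching all
tables is an error, not a warning. The replacement strings for the seed
ions are the standard SMILES for those ions.

## Synthetic corpus

The fixture generator emulates the notation space, not chemistry: random
chains (≤ 6 main-chain atoms, short branches, optional ring, occasional
`~`-bonded bracket-atom pairs), planted annotations including
surface-pointer pairs with recorded targets, random formula trees
(nesting ≤ 3, counts ≤ 5, occasional isotopes and charges), composites,
and mixed multi-component notations with multipliers. Ground truth
(component counts, multipliers, atom/bond counts, anchors, pointer
targets, flattened maps) is recorded during generation by independent
bookkeeping that never touches the parser. The mutation operator applies
exactly one corruption — unbalancing a brace, inserting `@` into a depth-0
SMILES region, rewriting a multiplier to `{1}`, prefixing a component to a
composite, stripping the bracket form off a `~` endpoint — and records the
error class the parser must raise.

Passing the corpus shows the grammar, anchoring rules, flattening algebra
and error taxonomy are implemented consistently at small scale. It says
nothing about chemical plausibility, about notations larger than the
generator's limits, or about the full external registries of predefined
aliases, dictionary keys and state/shape terms, of which only seeds ship.

## Problem sizes and determinism

Property suites run 500 fuzzed formulas, 550 fuzzed notations across all
profiles, 500 mutations, and ring expansions for k = 2…6; hypothesis
strategies are derandomized. The whole suite completes in a few seconds.
The acceptance script's `--seed` drives the fuzzed self-check; the target
quantities themselves are deterministic parses of fixed worked-example
notations.

## Known limitations

* No canonicalization: two encodings of one molecule are not identified
  at the graph level (formula-level matching is provided instead).
* No CIP verification of stereodescriptors, no aromaticity perception, no
  valence enforcement beyond hydrogen materialization.
* Molecular-detail (`!p`, `!m`, `!H`, `!I`) and miscellaneous annotations
  are stored and round-tripped opaquely; their geometry semantics are out
  of scope.
* Symbolic ranges (`n=4-16`) are never enumerated into explicit molecules.
* The `&` bond and unknown registry entries are carried, with warnings,
  rather than interpreted.
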