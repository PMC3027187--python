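# Seed registry of predefined annotation-dictionary keys.
# Format: key<TAB>description. The full predefined registry is an external,
# extensible resource; unknown keys warn rather than fail.
sfn	stoichiometric formula of a substrate/surface material
i	signed relative pointer to the atomic node carrying the full description
n	repeat or atom count; an integer or an inclusive integer range lo-hi
c	complete notation (recursive), e.g. a ligand of a coordination center
e	electron/charge detail, e.g. + for a delocalized positive ring charge
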