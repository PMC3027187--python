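# Seed table of predefined aliases (editable placeholder; the complete
# predefined registry is an external resource). Format:
# alias<TAB>replacement component notation. Lookup keys include any charge
# suffix, so ions of the same parent stay distinct.
bmim(1+)	CCCCn1cc[n+](C)c1
emim(1+)	CCn1cc[n+](C)c1
NTf2(1-)	O=S(=O)(C(F)(F)F)[N-]S(=O)(=O)C(F)(F)F
BF4(1-)	F[B-](F)(F)F
PF6(1-)	F[P-](F)(F)(F)(F)F
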