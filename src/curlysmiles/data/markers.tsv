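# Seed registry of state-and-shape (two lowercase letters) and miscellaneous
# two-letter annotation markers. Format: marker<TAB>description. The full
# vocabularies are external, extensible registries; unknown markers warn.
aq	aqueous solution
am	amorphous phase
cr	crystalline phase
lc	liquid-crystalline phase
np	nanoparticle
nw	nanowire
nt	nanotube
tf	thin film
sc	supercritical fluid
gl	glassy state
Mi	miscellaneous interest (generic seed entry)
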