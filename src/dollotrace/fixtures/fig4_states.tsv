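# Functional states of the Krt24-flanking genes Krt223 and Krt224 in
# tetrapod genomes, restricted to species with an explicitly reported
# state: Krt223 is intact in strepsirrhine primates (galago, sifaka) and
# the tree shrew, while the human genome carries only a pseudogene remnant
# (KRT223P). Krt224 lies 3' of Krt24 in the platypus and marsupials
# (Tasmanian devil) but is missing from the investigated placentals
# (primates, tree shrew, cattle); a Krt224 pseudogene remnant exists in
# the human genome. Cells without a reported state are UNKNOWN.
species	KRT223	KRT224
platypus	UNKNOWN	INTACT
Tasmanian_devil	UNKNOWN	INTACT
human	PSEUDOGENE	PSEUDOGENE
tarsier	UNKNOWN	ABSENT
galago	INTACT	ABSENT
sifaka	INTACT	ABSENT
tree_shrew	INTACT	ABSENT
cattle	UNKNOWN	ABSENT
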