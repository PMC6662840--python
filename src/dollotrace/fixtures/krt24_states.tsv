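# Functional state of Krt24 across mammals. Cells cover only species whose
# state is explicitly reported in the comparative-genomics screen this
# package models: Krt24 inactivated in the genus Camelus (dromedary,
# Bactrian camel, wild camel) but intact in the alpaca; lost in cetaceans
# (gene remnants with disrupted reading frames in dolphin and other
# cetaceans) after the split from the hippopotamus lineage, which kept an
# intact gene; nonfunctional in the walrus, northern fur seal and
# California sea lion (clade Otaroidea) while earless seals (harbor seal,
# Phocidae) kept an intact gene; conserved in human, mouse, blind mole rat
# and cattle. Unlisted tree species have no reported state.
species	KRT24
human	INTACT
mouse	INTACT
blind_mole_rat	INTACT
cattle	INTACT
hippopotamus	INTACT
sperm_whale	PSEUDOGENE
dolphin	PSEUDOGENE
alpaca	INTACT
dromedary	PSEUDOGENE
bactrian_camel	PSEUDOGENE
wild_camel	PSEUDOGENE
harbor_seal	INTACT
walrus	PSEUDOGENE
fur_seal	PSEUDOGENE
sea_lion	PSEUDOGENE
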