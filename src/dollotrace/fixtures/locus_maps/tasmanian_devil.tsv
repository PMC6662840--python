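# Tasmanian devil (marsupial) keratin locus: Krt224 on the 3' side of
# Krt24. Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
tasmanian_devil	chr3	Krt222	100000	105000	+
tasmanian_devil	chr3	Krt24	120000	125000	+
tasmanian_devil	chr3	Krt224	140000	145000	+
tasmanian_devil	chr3	Krt12	160000	165000	+
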