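# Cattle keratin locus: Krt24 conserved, no Krt223/Krt224.
# Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
cattle	chr19	Krt222	100000	105000	+
cattle	chr19	Krt24	120000	125000	+
cattle	chr19	Krt25	140000	145000	+
cattle	chr19	Krt12	160000	165000	+
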