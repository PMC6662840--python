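# Chicken keratin locus: both conserved anchors present but no Krt24
# homolog between them. Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
chicken	chr27	Krt222	100000	105000	+
chicken	chr27	Krt12	120000	125000	+
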