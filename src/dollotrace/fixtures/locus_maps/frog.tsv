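# Frog keratin locus: a Krt24-like gene but no 1:1 Krt24 ortholog besides
# Krt222 in amphibians. Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
frog	scaffold_f	Krt222	100000	105000	+
frog	scaffold_f	Krt24-like	120000	125000	+
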