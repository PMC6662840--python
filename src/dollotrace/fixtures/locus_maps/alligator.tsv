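# Alligator keratin locus: a Krt24-like gene located between Krt222 and
# Krt10; positional orthology to mammalian Krt24 is unresolved.
# Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
alligator	scaffold_a	Krt222	100000	105000	+
alligator	scaffold_a	Krt24-like	120000	125000	+
alligator	scaffold_a	Krt10	140000	145000	+
alligator	scaffold_a	Krt12	160000	165000	+
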