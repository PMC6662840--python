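# Galago (strepsirrhine primate) keratin locus: Krt223 on the 5' side of
# Krt24. Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
galago	scaffold_g	Krt222	100000	105000	+
galago	scaffold_g	Krt223	120000	125000	+
galago	scaffold_g	Krt24	140000	145000	+
galago	scaffold_g	Krt25	160000	165000	+
galago	scaffold_g	Krt12	180000	185000	+
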