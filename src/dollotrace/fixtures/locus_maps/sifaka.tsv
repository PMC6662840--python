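# Sifaka (strepsirrhine primate) keratin locus: Krt223 on the 5' side of
# Krt24. Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
sifaka	scaffold_s	Krt222	100000	105000	+
sifaka	scaffold_s	Krt223	120000	125000	+
sifaka	scaffold_s	Krt24	140000	145000	+
sifaka	scaffold_s	Krt25	160000	165000	+
sifaka	scaffold_s	Krt12	180000	185000	+
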