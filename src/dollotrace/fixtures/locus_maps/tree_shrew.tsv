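# Tree shrew keratin locus: Krt223 retained next to Krt24; no Krt224.
# Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
tree_shrew	scaffold_t	Krt222	100000	105000	+
tree_shrew	scaffold_t	Krt223	120000	125000	+
tree_shrew	scaffold_t	Krt24	140000	145000	+
tree_shrew	scaffold_t	Krt25	160000	165000	+
tree_shrew	scaffold_t	Krt12	180000	185000	+
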