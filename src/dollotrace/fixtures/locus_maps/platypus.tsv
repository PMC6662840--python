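# Platypus keratin locus: three Krt24-like genes (1:1 orthology to Krt24
# unresolved in monotremes) with Krt224 on their 3' side, inside the
# KRT222-KRT12 window. Coordinates are illustrative spacing.
species	region	symbol	start	end	strand
platypus	contig_k1	Krt222	100000	105000	+
platypus	contig_k1	Krt24-like	120000	125000	+
platypus	contig_k1	Krt24-like	140000	145000	+
platypus	contig_k1	Krt24-like	160000	165000	+
platypus	contig_k1	Krt224	180000	185000	+
platypus	contig_k1	Krt12	200000	205000	+
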