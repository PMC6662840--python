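# Human keratin locus inside the KRT222-KRT12 window (see also the
# human_keratin_locus fixture); KRT223/KRT224 survive only as pseudogene
# remnants and are not listed as genes. Coordinates are illustrative.
species	region	symbol	start	end	strand
human	chr17	KRT222	100000	105000	-
human	chr17	KRT24	120000	125000	-
human	chr17	KRT25	140000	145000	-
human	chr17	KRT26	160000	165000	-
human	chr17	KRT27	180000	185000	-
human	chr17	KRT28	200000	205000	-
human	chr17	KRT10	220000	225000	-
human	chr17	KRT12	240000	245000	-
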