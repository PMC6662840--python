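# Human type I keratin gene cluster on chromosome 17q21, restricted to
# the window bordered by KRT222 and KRT12 that the comparative screen
# uses: KRT24 is flanked by KRT222 and KRT25, followed by the inner-root-
# sheath keratins KRT26-KRT28, epidermal KRT10 and corneal KRT12.
# Coordinates are approximate spacing for illustration, not assembly
# coordinates.
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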