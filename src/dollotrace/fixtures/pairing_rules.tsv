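# Default type I -> type II keratin pairing preferences for corneal and
# epidermal epithelia. K24 is treated as a promiscuous type I partner:
# K3 is the prime corneal candidate, with K4 and K5 as fallbacks where
# K3 is missing (e.g. mouse cornea). Editable by users.
typeI	typeII	rank	promiscuous
K14	K5	1	false
K12	K3	1	false
K10	K1	1	false
K10	K2	2	false
K24	K3	1	true
K24	K4	2	true
K24	K5	3	true
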