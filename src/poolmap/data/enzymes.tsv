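name	site	cut_offset
ClaI	ATCGAT	2
XbaI	TCTAGA	1
XhoI	CTCGAG	1
KpnI	GGTACC	5
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
EcoRV	GATATC	3
NotI	GCGGCCGC	2
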