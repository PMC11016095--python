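name	site	cut_offset
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
XhoI	CTCGAG	1
SalI	GTCGAC	1
PstI	CTGCAG	5
SacI	GAGCTC	5
KpnI	GGTACC	5
SmaI	CCCGGG	3
XbaI	TCTAGA	1
SpeI	ACTAGT	1
NcoI	CCATGG	1
NdeI	CATATG	2
NheI	GCTAGC	1
BglII	AGATCT	1
EcoRV	GATATC	3
ScaI	AGTACT	3
StuI	AGGCCT	3
ApaI	GGGCCC	5
SphI	GCATGC	5
ClaI	ATCGAT	2
DraI	TTTAAA	3
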