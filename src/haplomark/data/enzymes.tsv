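# Default restriction-enzyme catalog for CAPS/dCAPS design and in-silico digestion.
# Recognition sequences and top-strand cut offsets follow the standard commercial
# (REBASE-style) definitions for common type II enzymes. Catalog order encodes the
# design preference (common, inexpensive cutters first); user catalogs override.
# Columns: name <TAB> IUPAC recognition <TAB> top-strand cut offset (bases from 5' end)
EcoRI	GAATTC	1
HindIII	AAGCTT	1
BamHI	GGATCC	1
TaqI	TCGA	1
DdeI	CTNAG	1
HinfI	GANTC	1
AluI	AGCT	2
MboI	GATC	0
RsaI	GTAC	2
HaeIII	GGCC	2
MseI	TTAA	1
NlaIII	CATG	4
HhaI	GCGC	3
HpaII	CCGG	1
BglI	GCCNNNNNGGC	7
BglII	AGATCT	1
PstI	CTGCAG	5
SacI	GAGCTC	5
KpnI	GGTACC	5
SmaI	CCCGGG	3
XbaI	TCTAGA	1
XhoI	CTCGAG	1
SalI	GTCGAC	1
NcoI	CCATGG	1
NdeI	CATATG	2
NheI	GCTAGC	1
SpeI	ACTAGT	1
SphI	GCATGC	5
StuI	AGGCCT	3
ScaI	AGTACT	3
SspI	AATATT	3
DraI	TTTAAA	3
EcoRV	GATATC	3
HpaI	GTTAAC	3
ClaI	ATCGAT	2
MluI	ACGCGT	1
AflII	CTTAAG	1
AgeI	ACCGGT	1
ApaI	GGGCCC	5
AvrII	CCTAGG	1
BclI	TGATCA	1
BsrGI	TGTACA	1
AatII	GACGTC	5
NsiI	ATGCAT	5
PvuI	CGATCG	4
PvuII	CAGCTG	3
NotI	GCGGCCGC	2
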