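# Transcription of the published table "Intragenic markers for the 14 NUE genes".
# One row per primer; marker-level fields are repeated on every row of a marker.
# reference_size encodings follow the source's footnote: for Indel markers
# "A (+d)"/"A (-d)" = reference-accession amplicon A with the elite Indel delta d;
# for CAPS/dCAPS "X/(a,b)" or "(a,b)/X" = reference pattern before the slash, elite
# pattern after it (a comma list = digested fragments, a bare number = uncut).
# The source prints the SBM1 enzyme as "BgI I", read here as BglI (GCCNNNN^NGGC).
# An empty field is "-". target_haplotypes is comma-joined.
gene	gene_label	variation_position	marker_type	marker_name	primer_role	primer_sequence	reference_size	enzyme	target_haplotypes
OsNPF6.1	NPF6.1	-1197	Indel	NPF6.1 5U ID	F	TAATGTCCTTTCCCGTGTT	220 (+20)	-	HapB
OsNPF6.1	NPF6.1	-1197	Indel	NPF6.1 5U ID	R	GTACTACTTCGGCTGTCC	220 (+20)	-	HapB
DNR1	DNR1	+2165	Indel	DNR1 I4 ID	F	CGTCAATTATGGTTACCTCTG	171 (-10)	-	HapB
DNR1	DNR1	+2165	Indel	DNR1 I4 ID	R	GCATCTCATAGAACTGAAGAAG	171 (-10)	-	HapB
MYB61	MYB61	+2346	Indel	MYB61 3U ID	F	ACTTGAATACAGGCATGGAA	205 (+26)	-	HapB
MYB61	MYB61	+2346	Indel	MYB61 3U ID	R	CGTTATGCTTGTTGCTTGA	205 (+26)	-	HapB
SBM1	SBM1	-325	Indel	SBM1 5U ID	F	TCGGGTGTACTACGGATC	90 (-8)	-	HapB
SBM1	SBM1	-325	Indel	SBM1 5U ID	R	GCACATACATATCAGGGA	90 (-8)	-	HapB
SBM1	SBM1	+865	CAPS	SBM1 E3 S	F	TCTTCAACTGGATCAACTTC	380/(100,280)	BglI	HapB,HapD
SBM1	SBM1	+865	CAPS	SBM1 E3 S	R	TACATCACGGTGGTCATC	380/(100,280)	BglI	HapB,HapD
NGR2	NGR2	-935	CAPS	NGR2 5U S	F	TCATTGACCTACGGTTGC	(249,24)/273	TaqI	HapB
NGR2	NGR2	-935	CAPS	NGR2 5U S	R	GCTGCTCCAACATCTTCT	(249,24)/273	TaqI	HapB
NGR2	NGR2	+1701	PARMS	NGR2 I3 S	FC	GAAGGTGACCAAGTTCATGCTAGTAGTACTACTTCGATTTGGTGCT	-	-	HapB
NGR2	NGR2	+1701	PARMS	NGR2 I3 S	FT	GAAGGTCGGAGTCAACGGATTAGTAGTACTACTTCGATTTGGTGCC	-	-	HapB
NGR2	NGR2	+1701	PARMS	NGR2 I3 S	R	GCAGTGCAGAGAGTAAAGTTTCAG	-	-	HapB
OsNR2	NR2	+2202	Indel	NR2 E4 ID	F	TCACGTCCATCGTTGAGA	120 (+12)	-	HapB
OsNR2	NR2	+2202	Indel	NR2 E4 ID	R	ACAGGCTCTTCTTGTCCAT	120 (+12)	-	HapB
NGR5	NGR5	-1565	Indel	NGR5 5U ID	F	AGAACACACGGGATAGGAT	210 (-13)	-	HapB,HapC,HapD
NGR5	NGR5	-1565	Indel	NGR5 5U ID	R	GAATCACTTGCTCGCTAGA	210 (-13)	-	HapB,HapC,HapD
NGR5	NGR5	+3326	PARMS	NGR5 I6 S	FC	GAAGGTGACCAAGTTCATGCTATCTCGCTGTCCTAAACGACTTCC	-	-	HapB
NGR5	NGR5	+3326	PARMS	NGR5 I6 S	FT	GAAGGTCGGAGTCAACGGATTATCTCGCTGTCCTAAACGACTTCT	-	-	HapB
NGR5	NGR5	+3326	PARMS	NGR5 I6 S	R	GAATTACGTACACCCTCCGTACTC	-	-	HapB
OsTCP19	TCP19	-2022	Indel	TCP19 5U ID	F	AACTCTTCAGGGTTCTTGC	231 (-29)	-	HapB
OsTCP19	TCP19	-2022	Indel	TCP19 5U ID	R	GTGCCGTGTCACATAGAG	231 (-29)	-	HapB
ARE1	ARE1	-393	Indel	ARE1 5U ID	F	CCGTGTCTTATCCACTCC	115 (+6)	-	HapB
ARE1	ARE1	-393	Indel	ARE1 5U ID	R	ATGGGGATCGATACGATG	115 (+6)	-	HapB
ARE1	ARE1	-723	CAPS	ARE1 5U S	F	TTAACACTTGTGGCAATGAC	320/(100,210)	DdeI	HapC
ARE1	ARE1	-723	CAPS	ARE1 5U S	R	CTAGTACCGTATTGGCTGTT	320/(100,210)	DdeI	HapC
DEP1	DEP1	+3454	Indel	DEP1 E5 ID	F	GACCAAGGTGCCTCAATT	1085 (-615)	-	HapB
DEP1	DEP1	+3454	Indel	DEP1 E5 ID	R	TTCAACCTCGTCTCATAGC	1085 (-615)	-	HapB
OsNAC42	NAC42	+3508	dCAPS	NAC42 3U S	F	TACGTGACTTCGACGGCtGA	(100,20)/120	DdeI	HapB
OsNAC42	NAC42	+3508	dCAPS	NAC42 3U S	R	ACGGTCCAAATGCTGCTTCG	(100,20)/120	DdeI	HapB
OsNLP4	NLP4	-1771	Indel	NLP4 5U ID	F	AAGTCCTTCCTAAACTGAGA	136 (-6)	-	HapB
OsNLP4	NLP4	-1771	Indel	NLP4 5U ID	R	GGTCTGTTCCAAACAAAGAT	136 (-6)	-	HapB
NRT1.1B	NRT1.1B	+2825	Indel	NRT1.1B I1 ID	F	CATATTTGTTGGCTGCTAAC	178 (+16)	-	HapB
NRT1.1B	NRT1.1B	+2825	Indel	NRT1.1B I1 ID	R	GGTGGTTCTAACGGTCAA	178 (+16)	-	HapB
TOND1	TOND1	-1205	Indel	TOND1 5U ID	F	TTTGGGTCCCTGACAATA	153 (+8)	-	HapB
TOND1	TOND1	-1205	Indel	TOND1 5U ID	R	TGGAACAACTCAAGTAGCA	153 (+8)	-	HapB
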