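# Transcription of the published table "Haplotypes of 14 NUE genes in the 36 rice
# accessions with reference genome". A trailing "*" on a haplotype call marks an entry
# printed in bold (elite) in the source; "n.d." = not determined. printed_count is the
# source's "No. of elite haplotypes" column, kept verbatim alongside recomputed counts
# so the known count discrepancies stay visible instead of being silently corrected.
accession	origin	subpopulation	OsNPF6.1	DNR1	MYB61	SBM1	NGR2	OsNR2	NGR5	OsTCP19	ARE1	DEP1	OsNAC42	OsNLP4	NRT1.1B	TOND1	printed_count
N22	India	cA	HapD	n.d.	n.d.	HapB*	HapE	HapB*	HapD	HapB*	n.d.	HapF	HapD	HapB*	n.d.	n.d.	4
Basmati 1	Pakistan	cB	HapA	HapC	HapB*	HapA	HapE	n.d.	HapA	n.d.	n.d.	HapA	HapE	HapA	HapA	n.d.	1
LJ	YN, China	GJ-adm	HapA	HapD	HapC	HapA	HapE	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
NamRoo	Thailand	GJ-sbtrp	HapA	HapA	HapC	HapA	HapE	HapA	HapA	HapA	n.d.	HapA	HapA	HapA	HapA	HapC	0
2428	JS, China	GJ-tmp	HapA	HapD	HapC	HapA	HapC	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
DHX2	HLJ, China	GJ-tmp	HapA	HapA	HapC	HapA	HapE	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
Kosh	Japan	GJ-tmp	HapA	HapA	HapA	HapA	HapC	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
KY131	Japan	GJ-tmp	HapA	HapA	HapC	HapA	HapC	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
NIP	Japan	GJ-tmp	HapA	HapA	HapA	HapA	HapC	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	0
ZH11	TJ, China	GJ-tmp	HapA	HapA	HapC	HapA	HapC	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
Lemont	United States	GJ-trp	HapA	HapD	HapC	HapD	HapE	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapA	HapC	0
HZ	China	XI	HapA	HapB*	HapB*	HapD	HapA	HapB*	HapD	HapB*	HapC*	HapC	HapC	HapB*	HapB*	HapB*	7
TFB	GD, China	XI	HapB*	HapB*	HapB*	HapC	HapB*	HapB*	HapD	HapA	HapC*	HapF	HapA	HapB*	HapB*	HapC	8
CN1	SC, China	XI-1A	HapB*	HapB*	HapB*	HapC	HapD	HapB*	HapE	HapA	HapC*	HapF	HapE	HapB*	HapB*	HapB*	8
D62	SC, China	XI-1A	HapB*	HapB*	HapB*	HapD	HapC	HapB*	HapD	HapA	HapC*	HapF	HapB*	HapB*	HapB*	HapB*	9
DG	FJ, China	XI-1A	HapC	HapB*	HapB*	HapC	HapD	HapB*	HapD	HapA	HapC*	HapD	HapD	HapB*	HapB*	HapC	6
FS32	n.d.	XI-1A	HapC	HapB*	HapB*	n.d.	HapA	HapB*	HapE	HapA	HapC*	HapD	n.d.	HapB*	HapB*	HapB*	7
G46	SC, China	XI-1A	HapB*	HapB*	HapB*	n.d.	HapA	HapB*	HapE	HapA	HapC*	HapF	HapE	HapB*	HapB*	HapC	7
II32	HN, China	XI-1A	HapB*	HapB*	HapB*	HapC	HapB*	HapB*	HapE	HapA	HapC*	HapD	HapA	HapB*	HapB*	HapC	8
ZS97	ZJ, China	XI-1A	HapB*	HapB*	HapB*	HapC	HapB*	HapB*	HapE	HapA	HapC*	HapD	HapA	HapB*	HapB*	HapC	8
9311	JS, China	XI-1B	HapA	HapB*	HapB*	HapC	HapA	HapB*	HapE	HapA	HapC*	HapD	HapD	HapB*	HapB*	HapB*	6
G8	GD, China	XI-1B	HapA	HapB*	HapB*	HapC	HapB*	HapB*	HapE	HapA	HapC*	HapC	HapD	HapB*	HapB*	HapB*	8
IR64	IRRI	XI-1B	HapA	HapB*	HapB*	HapD	HapB*	HapB*	HapC	HapB*	HapB*	HapE	HapB*	HapB*	HapB*	HapB*	10
J4115	HN, China	XI-1B	HapA	HapB*	HapB*	HapD	HapE	HapB*	HapB*	HapA	HapB*	HapC	HapB*	HapB*	HapB*	HapB*	9
R498	SC, China	XI-1B	HapC	HapB*	HapB*	HapD	HapA	HapB*	HapB*	HapA	HapB*	HapC	HapB*	HapB*	HapB*	HapB*	9
R527	JX China	XI-1B	HapA	HapB*	HapB*	HapD	HapB*	HapB*	HapB*	HapA	HapB*	HapE	HapB*	HapB*	HapB*	HapB*	10
S548	SC, China	XI-1B	HapA	HapB*	HapB*	HapD	HapA	HapA	HapB*	HapB*	HapB*	HapC	HapC	HapB*	HapB*	HapB*	8
Y3551	SC, China	XI-1B	HapA	HapB*	HapB*	HapD	HapA	HapB*	HapB*	HapA	HapC*	HapC	HapE	HapB*	HapB*	HapB*	8
Y58S	HN, China	XI-1B	HapA	HapB*	HapB*	HapD	HapE	HapB*	HapA	HapA	HapC*	HapC	HapB*	HapB*	HapB*	HapB*	7
TM	Madagascar	XI-2	HapA	HapB*	n.d.	HapC	HapE	HapB*	HapD	HapB*	n.d.	HapD	HapD	HapB*	HapB*	HapB*	6
TUMBA	Indonesia	XI-3	HapA	HapB*	HapB*	HapC	HapD	HapB*	HapD	HapB*	n.d.	HapE	HapB*	HapB*	HapB*	HapB*	8
FH838	SC, China	XI-adm	HapA	HapB*	HapB*	HapD	HapA	HapB*	HapB*	HapA	HapB*	HapE	HapB*	HapB*	HapB*	HapC	8
G630	Guyana	XI-adm	HapA	HapB*	HapB*	HapD	HapA	HapB*	HapB*	HapA	n.d.	HapC	HapE	HapB*	HapB*	HapC	6
MH63	FJ, China	XI-adm	HapA	HapB*	HapB*	HapD	HapA	HapB*	HapB*	HapA	HapB*	HapC	HapE	HapB*	HapB*	HapB*	8
WSSM	GD, China	XI-adm	HapA	HapB*	HapB*	HapD	HapA	HapB*	HapD	HapA	HapC*	HapE	HapB*	HapB*	HapB*	n.d.	7
YX1	SC, China	XI-adm	HapB*	HapB*	HapB*	HapC	HapB*	HapB*	HapB*	HapA	HapC*	HapD	HapA	HapB*	HapB*	HapB*	10
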