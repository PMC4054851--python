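clone_id	genes	locus	md_count
NL1-CJ4R (C)	NKIRAS1/RPL15	3p24.2	13
NL6-FJ5R (C)	LRRN1	3p26.2	10
NL3-CA11RS	LRRC3B	3p24	10
NLJ-003RD	CTDSPL	3p21.3	8
NL3003R (U)	GORASP1/TTC21A	3p22-p21.33	8
NRLA404R (U)	VHL	3p25.3	7
NR1-XM13C	IQSEC1	3p25.2	6
NL1-BA6R	FOXP1	3p14.1	6
NR1-AN24RS	ABHD5/C3orf77	3p21	5
NL3A006R (D)	NBEAL2	3p21.31	5
NL3A001R (D)	GNAI2	3p21.31	5
NR1-NC7RS	PPM1M	3p21.2	5
NR1-NJ9R (C)	PRICKLE2	3p14.1	5
HSJ4-AB7R (C)	RPL32/IQSEC1	3p25.2	4
NL4-DP2RS	FGD5	3p25.1	4
NL4-AP18R (C)	PLCL2	3p24.3	4
NL4-BC8R (C)	ALDH1L1	3q21.3	4
NL1A079R (D)	EPHB1	3q21-q23	4
NR1-PD1R	ZIC4	3q24	4
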