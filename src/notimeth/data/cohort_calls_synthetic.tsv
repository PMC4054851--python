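clone_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12	S13	S14	S15	S16	S17	S18	S19	S20	S21	S22	S23
NL1-CJ4R (C)	MD	RET	MD	RET	RET	RET	MD	MD	RET	MD	MD	RET	MD	RET	MD	MD	MD	MD	MD	RET	RET	MD	RET
NL6-FJ5R (C)	RET	RET	MD	RET	MD	RET	MD	MD	RET	RET	MD	RET	RET	RET	RET	MD	MD	RET	RET	MD	MD	MD	RET
NL3-CA11RS	MD	RET	MD	MD	MD	RET	RET	MD	RET	RET	MD	RET	RET	RET	RET	MD	MD	RET	RET	RET	RET	MD	MD
NLJ-003RD	RET	RET	RET	MD	RET	RET	MD	MD	RET	MD	MD	RET	RET	RET	RET	MD	MD	RET	RET	RET	MD	RET	RET
NL3003R (U)	RET	RET	RET	RET	RET	RET	RET	MD	RET	RET	MD	RET	MD	RET	MD	MD	MD	MD	MD	RET	RET	RET	RET
NRLA404R (U)	MD	RET	RET	RET	MD	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	MD	RET	RET	MD	MD	MD	MD
NR1-XM13C	RET	RET	RET	MD	RET	RET	RET	MD	RET	RET	MD	RET	RET	RET	RET	MD	MD	RET	RET	RET	RET	MD	RET
NL1-BA6R	MD	RET	RET	RET	RET	RET	RET	MD	RET	RET	MD	RET	RET	RET	RET	MD	MD	RET	RET	RET	RET	MD	RET
NR1-AN24RS	RET	RET	NA	RET	RET	RET	RET	MD	RET	RET	MD	RET	RET	RET	RET	MD	MD	RET	RET	RET	RET	MD	RET
NL3A006R (D)	RET	RET	RET	MD	RET	RET	RET	MD	RET	RET	MD	RET	RET	RET	RET	RET	MD	RET	RET	RET	RET	MD	RET
NL3A001R (D)	RET	RET	RET	RET	MD	RET	RET	MD	RET	MD	MD	RET	RET	RET	RET	RET	MD	RET	RET	RET	RET	RET	RET
NR1-NC7RS	RET	RET	RET	RET	RET	RET	RET	MD	RET	RET	RET	RET	MD	RET	MD	MD	MD	RET	RET	RET	RET	RET	RET
NR1-NJ9R (C)	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	MD	MD	MD	MD	MD	RET
HSJ4-AB7R (C)	MD	MD	MD	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	NA	RET	RET	RET	MD
NL4-DP2RS	RET	RET	RET	MD	MD	MD	MD	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET
NL4-AP18R (C)	RET	RET	RET	RET	RET	RET	RET	MD	MD	MD	MD	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET
NL4-BC8R (C)	RET	RET	RET	RET	RET	RET	AD	RET	RET	RET	RET	MD	MD	MD	MD	RET	RET	RET	RET	RET	RET	RET	RET
NL1A079R (D)	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	MD	MD	MD	MD	RET	RET	RET	RET
NR1-PD1R	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	RET	MD	MD	MD	MD
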