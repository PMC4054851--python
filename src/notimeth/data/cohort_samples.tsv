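sample_id	histology	stage	tnm
S01	ccRCC	I	T1N0M0
S02	ccRCC	I	T1N0M0
S03	ccRCC	I	T1N0M0
S04	ccRCC	I	T1N0M0
S05	ccRCC	I	T1N0M0
S06	ccRCC	I	T1N0M0
S07	ccRCC	I	T1N0M0
S08	ccRCC	II	T2N0M0
S09	ccRCC	II	T2N0M0
S10	ccRCC	II	T2N0M0
S11	ccRCC	II	T2N0M0
S12	ccRCC	II	T2N0M0
S13	ccRCC	II	T2N0M0
S14	ccRCC	II	T2N0M0
S15	ccRCC	II	T2N0M0
S16	ccRCC	II	T2N0M0
S17	ccRCC	III	T3N0(1)M0
S18	ccRCC	III	T3N0(1)M0
S19	ccRCC	III	T3N0(1)M0
S20	ccRCC	III	T3N0(1)M0
S21	ccRCC	III	T3N0(1)M0
S22	ccRCC	III	T3N0(1)M0
S23	ccRCC	III	T3N0(1)M0
P01	pRCC	I	T1N0M0
P02	pRCC	I	T1N0M0
P03	pRCC	I	T1N0M0
P04	pRCC	I	T1N0M0
P05	pRCC	I	T1N0M0
P06	pRCC	II	T2N0M0
P07	pRCC	II	T2N0M0
P08	pRCC	II	T2N0M0
P09	pRCC	II	T2N0M0
P10	pRCC	III	T3N0(1)M0
P11	pRCC	III	T3N0(1)M0
P12	pRCC	III	T3N0(1)M0
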