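group	csm_id	motif	note
CYP2A	7	Absent
CYP2A	8	193-YKDKEFLS-200
CYP2A	9	217-GQLYEMFSSVM-227
CYP2A	10	Absent
CYP2A	11	260-DPNSP-264
CYP2A	2A-specific-1	204-MMLGIFQF-211	subfamily-specific motif
CYP2A	2A-specific-2	243-GLENF-247	subfamily-specific motif
CYP2D	7	180-KAVSN-184
CYP2D	8	192-GRRFEYDDP-200
CYP2D	9	225-NAVPVLLHIPALAGK-239
CYP2D	10	Absent
CYP2D	11	Absent
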