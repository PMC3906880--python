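cluster	KM_1	KM_2	KM_3	KM_4	KM_5	KM_6	KM_7	KM_8
CLMM_WT_1	27	0	0	0	10	0	0	0
CLMM_WT_2	11	10	14	0	0	6	0	0
CLMM_WT_3	13	0	10	0	2	0	0	0
CLMM_WT_4	0	0	3	8	0	0	0	0
CLMM_WT_5	0	0	6	0	0	32	0	0
CLMM_WT_6	0	9	0	0	0	51	0	0
CLMM_WT_7	0	0	0	0	0	1	16	0
CLMM_WT_8	1	9	0	0	0	7	0	10
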