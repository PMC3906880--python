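cluster	Both_1	Both_2	Both_3	Both_4	Both_5	Both_6	Both_7	Both_8
CLMM_WT_1	13	1	3	0	2	0	0	3
CLMM_WT_2	21	33	0	0	0	0	0	0
CLMM_WT_3	3	0	22	0	0	0	0	1
CLMM_WT_4	0	0	0	11	0	0	0	0
CLMM_WT_5	0	2	0	0	30	2	0	0
CLMM_WT_6	0	1	0	0	4	50	0	0
CLMM_WT_7	0	0	0	0	0	0	17	0
CLMM_WT_8	0	4	0	0	2	8	0	23
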