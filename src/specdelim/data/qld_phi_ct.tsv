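locus	k	phi_ct
coi	2	0.30627
coi	3	0.34669
coi	5	0.59395
coi	6	0.71038
coi	8	0.68975
coi	10	0.62057
coi	11	0.72424
coi	13	0.83371
16s	2	0.33209
16s	3	0.42938
16s	5	0.63887
16s	6	0.80942
16s	8	0.82056
16s	10	0.77748
16s	11	0.86880
16s	13	0.92958
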