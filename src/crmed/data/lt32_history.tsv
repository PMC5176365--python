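cohort_id	dose	n	n_success	forced
1	2.0	3	3	0
2	1.0	3	2	0
3	2.0	3	2	0
4	2.5	3	3	0
5	2.5	3	3	0
6	2.5	3	3	0
7	2.0	3	3	0
8	2.0	3	3	0
9	2.0	3	2	0
10	2.5	2	2	0
11	2.0	1	1	1
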