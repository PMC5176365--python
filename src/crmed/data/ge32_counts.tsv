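dose	n_success	n_failure
1.0	17	1
1.5	0	0
2.0	6	0
2.5	0	0
3.0	0	0
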