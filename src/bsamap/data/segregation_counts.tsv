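label	total	n_fuzzless	n_fuzzy	expected_fuzzless	expected_fuzzy
F2	4010	3004	1006	3	1
BC1	607	315	292	1	1
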