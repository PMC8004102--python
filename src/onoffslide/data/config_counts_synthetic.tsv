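# SYNTHETIC configuration counts sampled from the package's ground-truth
# fixture model (make_reference_fixture, seed 0). NOT experimental data.
state	config_index	count
repressed	1	133
repressed	2	1
repressed	3	1
repressed	4	15
repressed	5	0
repressed	6	0
repressed	7	0
repressed	8	0
weakly_activated	1	77
weakly_activated	2	11
weakly_activated	3	11
weakly_activated	4	42
weakly_activated	5	3
weakly_activated	6	4
weakly_activated	7	2
weakly_activated	8	0
activated	1	27
activated	2	8
activated	3	20
activated	4	55
activated	5	20
activated	6	5
activated	7	11
activated	8	4
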