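# Restriction-enzyme accessibility fold-changes (sticky N-3 mutant / wild type)
# in the activated promoter state, mean +- sd of two biological replicates.
mutant	site	mean	sd
1	N-2	0.68	0.04
1	N-3	0.52	0.23
2	N-2	0.74	0.08
2	N-3	0.62	0.13
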