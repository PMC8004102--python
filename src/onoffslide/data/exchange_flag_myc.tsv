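# Histone H3 exchange summary values, repressed promoter state.
# g_replicate: log2 Flag(N-1)/Flag(N-2) replicates at one measurement time.
# h_point: normalized log2 Flag/Myc at N-1 over time, one shared independent sd.
# NOTE: the four h measurement times below are ASSUMED values (the modelled
# summary does not print them); replace with transcribed times if available.
record	value	time_h	sd
g_replicate	0.591	2.0	
g_replicate	0.483	2.0	
h_point	-0.417	0.5	0.4
h_point	1.24	1.0	0.4
h_point	1.87	2.0	0.4
h_point	2.60	4.0	0.4
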