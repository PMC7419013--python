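stage	n_cells	merged_fc	common_covered	stage_fc_fraction
early	4	18	5971	0.002344665885
late	4	18	5752	0.001390820584
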