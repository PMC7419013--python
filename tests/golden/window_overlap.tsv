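a	b	n_a_specific	n_shared	n_b_specific
early	late	0	18	0
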