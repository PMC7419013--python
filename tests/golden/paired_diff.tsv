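pair_id	member_a	member_b	diff_whole_genome
p0	t00	t01	0.0003378983346
p1	t02	t03	-0.0001188685901
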