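class	n_fc_in	n_fc_total	n_bg_in	n_bg_total	log2_enrichment
ALR	0	18	256	10000	
Alu	0	18	919	10000	
CGI	1	18	107	10000	2.376320392
ERV1	1	18	275	10000	1.01449957
ERVK	1	18	100	10000	2.473931188
ERVL	0	18	206	10000	
ERVL-MaLR	0	18	367	10000	
L1	8	18	1671	10000	1.41129136
L2	1	18	291	10000	0.9329120352
MIR	0	18	323	10000	
SVA	0	18	59	10000	
TTS-region	0	18	261	10000	
exon	1	18	287	10000	0.9528804514
intron	7	18	3096	10000	0.328952544
promoter	1	18	317	10000	0.809448348
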