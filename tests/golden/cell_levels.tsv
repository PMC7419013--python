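cell_id	stage	level
t00	early	0.001941747573
t01	early	0.001603849238
t02	early	0.001373154823
t03	early	0.001492023413
t04	late	0.001385521302
t05	late	0.001724137931
t06	late	0.001382807098
t07	late	0.001507945714
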