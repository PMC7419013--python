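cell_id	treatment	conversion_rate	background_rate	cpg_ge1x	cpg_ge3x	cpg_ge5x	n_fc	n_unmod	abundance
t00	treated	0.7621359223	0.01050248412	9942	8811	5596	17	8738	0.001709917522
t01	treated	0.8252427184	0.0119433327	9936	8789	5681	14	8715	0.001409017713
t02	treated	0.7990654206	0.01183918962	9931	8803	5700	12	8727	0.001208337529
t03	treated	0.8341708543	0.01229665685	9921	8762	5673	13	8700	0.001310351779
t04	treated	0.8186813187	0.01267930328	9930	8699	5550	12	8649	0.001208459215
t05	treated	0.8316326531	0.01034308779	9932	8765	5648	15	8685	0.001510269835
t06	treated	0.7947368421	0.01048322064	9923	8744	5525	12	8666	0.0012093117
t07	treated	0.75	0.01113686108	9926	8681	5566	13	8608	0.001309691719
u00	untreated	0.009174311927	0.01211538462	9928	8684	5522	0	8626	0
u01	untreated	0.01363636364	0.01226564983	9944	8739	5604	0	8685	0
u02	untreated	0.02	0.01125007856	9933	8728	5583	0	8664	0
u03	untreated	0.01990049751	0.01058897243	9920	8688	5582	0	8644	0
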