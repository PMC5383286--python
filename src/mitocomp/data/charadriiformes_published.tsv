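suborder	family	species	accession	size_bp	pct_A	pct_T	pct_G	pct_C	at_content	at_skew	gc_skew
Charadrii	Haematopodidae	Haematopus ater	AY074886	16791	31.59	23.62	13.67	31.12	55.21	0.14	-0.39
Charadrii	Recurvirostridae	Recurvirostra avosetta	KP757766	16897	31.72	23.59	13.56	31.13	55.31	0.15	-0.39
Charadrii	Charadriidae	Vanellus cinereus	KM404175	17074	31.63	23.53	13.77	31.08	55.15	0.15	-0.39
Charadrii	Charadriidae	Vanellus cinereus	KM873665	17135	31.46	23.69	13.98	30.87	55.14	0.14	-0.38
Charadrii	Charadriidae	Vanellus vanellus	KM577158	16795	31.44	24.03	13.76	30.77	55.47	0.13	-0.38
Scolopaci	Jacanidae	Jacana jacana	KJ631049	16975	31.88	24.35	13.15	30.62	56.23	0.13	-0.40
Scolopaci	Jacanidae	Jacana spinosa	KJ631048	17079	31.54	24.86	13.09	30.42	56.45	0.12	-0.40
Scolopaci	Scolopacidae	Scolopax rusticola	KM434134	16984	31.79	25.02	13.34	29.85	56.81	0.12	-0.38
Scolopaci	Scolopacidae	Arenaria interpres	AY074885	16725	30.64	24.71	13.94	30.72	55.34	0.11	-0.38
Scolopaci	Scolopacidae	Eurynorhynchus pygmeus	KP742478	16707	31.29	24.85	13.84	30.02	56.14	0.11	-0.37
Scolopaci	Scolopacidae	Gallinago stenura	KY056596	16899	32.21	26.14	12.88	28.77	58.35	0.10	-0.38
Lari	Laridae	Chroicocephalus brunnicephalus	JX155863	16769	30.70	24.03	14.16	31.11	54.73	0.12	-0.37
Lari	Laridae	Chroicocephalus ridibundus	KM577662	16807	30.81	23.97	14.16	31.06	54.78	0.12	-0.37
Lari	Laridae	Chroicocephalus saundersi	JQ071443	16725	30.41	23.98	14.39	31.21	54.39	0.12	-0.37
Lari	Laridae	Larus crassirostris	KM507782	16746	30.62	24.34	14.13	30.91	54.96	0.11	-0.37
Lari	Laridae	Larus dominicanus	AY293619	16701	30.54	24.45	14.13	30.88	54.98	0.11	-0.37
Lari	Laridae	Ichthyaetus relictus	KC760146	16586	30.62	24.38	14.07	30.93	55.00	0.11	-0.37
Lari	Laridae	Sternula albifrons	KT350612	16357	31.11	26.12	13.74	29.03	57.22	0.09	-0.36
Lari	Stercorariidae	Stercorarius maccormicki	KM401546	16669	30.94	24.39	13.82	30.85	55.34	0.12	-0.38
Lari	Alcidae	Synthliboramphus antiquus	AP009042	16730	31.10	24.75	13.56	30.60	55.85	0.11	-0.39
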