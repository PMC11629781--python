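# Thaliacea forward-primer-region states: 15 COI sequences from 12
# species (six doliolids, five salps, one pyrosome), with states at the
# 13 non-conserved positions of the 26-nt forward primer region
# (blank = conserved).  expected_ml / expected_xt are the published
# mismatch totals vs mlCOIintF / mlCOIintF-XT (test oracle; recomputed).
accession	species	p1	p2	p3	p4	p5	p6	p7	p9	p12	p15	p16	p18	p24	expected_ml	expected_xt
OP437494	Dolioletta advena	A						A							2	1
OP437493	Dolioletta advena	A						A			G				3	2
OP437492	Dolioletta advena	A						A							2	1
OP437491	Dolioletta gegenbauri	A						A	G	G					4	2
OP437490	Doliolina krohni	A					G			G					3	2
OP437489	Doliolina muelleri	A						A			G		C		4	2
OP437495	Doliolum nationalis			G				A	G	G			C		5	2
AB176541	Doliolum nationalis			G				A	G	G			C		5	2
OP437487	Doliolum denticulatum	A						A	G	G	G				5	3
OP437488	Pyrosoma atlanticum	A						A	G		C		G	A	6	4
MT998285	Thalia longicauda	T	C		T	G		A			C	A	C		8	5
MH626415	Thalia democratica	T	C		T	G		A	G			A			7	5
KT818686	Brooksia lacromae	T	C		T	G		A				A	C		7	4
LC333181	Salpa fusiformis	T	C		T	G				G		A			6	4
LC333180	Salpa thompsoni	T	C		T	G		A				A		A	7	5
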