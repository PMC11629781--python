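# Appendicularia forward-primer-region states: 21 COI sequences from 14
# species, with states at the 14 non-conserved positions of the 26-nt
# forward primer region (blank = conserved, i.e. matching both forward
# primers).  polyT marks species whose COI region carries homopolymeric
# poly-T inserts.  expected_ml / expected_xt are the published mismatch
# totals vs mlCOIintF / mlCOIintF-XT (test oracle; always recomputed).
# Note: the PP339661 (O. albicans) mlCOIintF-only G is placed at #18
# (mlCOIintF W / Leray XT inosine); this is the only placement consistent
# with both the published totals (5/2) and the one-primer-only markup.
accession	species	p1	p3	p4	p5	p6	p7	p9	p12	p15	p16	p18	p22	p23	p24	expected_ml	expected_xt	polyT
SCLE01415711	Bathochordaeus stygius	A		T			A		G		A				A	6	3	
SCLF01725989	Mesochordaeus erythrocephalus	A		T			A	G	G		A					6	3	
PP339655	Megalocercus abyssorum	A		T		C	A	G	G		A					7	4	
LC222754	Oikopleura longicauda			T			A	G	G		A					5	2	
SCLD01101138	Oikopleura longicauda			T			A	G	G		A					5	2	
PP339656	Oikopleura longicauda			T					G		A					3	1	
PP339657	Oikopleura longicauda		C	T					G	C	A				A	6	4	
PP339658	Oikopleura longicauda	A		T					G		A					4	2	
PP339659	Oikopleura fusiformis		C	T					G	G	A	G	G	T		8	5	
SAMN00177767	Oikopleura dioica	A		T			A		G	C	A					6	3	X
PP339660	Oikopleura dioica	A		T			A			C	A					5	3	X
GCJN01047493	Oikopleura dioica	A		T					G		A					4	2	X
PP339661	Oikopleura albicans		G	T			A		G			G				5	2	X
PP339662	Stegosoma magnum	A		T			A		G		A	C				6	2	X
PP339663	Appendicularia sicula	A														1	1	X
PP339664	Fritillaria borealis sargassi	A									T	G				3	1	X
PP339665	Fritillaria pellucida	A	G				A				T				A	5	3	X
PP339666	Fritillaria formica tuberculata	A		T	G											3	3	X
PP339667	Kowalevskia tenuis	A	G	G	G	G		G			T					7	6	
PP339668	Kowalevskia oceanica	A		G	G	G										4	4	
PP339669	Kowalevskia oceanica	A		G	G	G										4	4	
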