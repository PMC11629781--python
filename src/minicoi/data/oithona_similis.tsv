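# Oithona similis forward-primer-region haplotype lineages (#I-#XIV).
# 247 aligned COI sequences collapse to 14 combinations of nucleotides at
# the eight variable positions of the 26-nt forward primer region.
# States are the concrete bases at positions #3 #6 #9 #12 #15 #18 #21 #24
# (1-based from the primer 5' end; #24 is the third nucleotide from the
# 3' end). n = number of sequences carrying the combination.
# expected_ml / expected_xt are the published per-lineage mismatch totals
# against mlCOIintF and mlCOIintF-XT, kept as an oracle for tests; the
# package always recomputes them.
label	n	area	p3	p6	p9	p12	p15	p18	p21	p24	expected_ml	expected_xt	accessions
#I	11	North Sea, Mediterranean	C	A	T	A	T	T	C	C	1	1	KU982714-16, KU982891-98
#II	89	Arctic Ocean, Norwegian Sea	T	A	T	G	T	G	C	C	2	0	KU982717-79, KU982859-61, KU982864-65, KU982867-81, KU982899, KU982918-20, KU982922, KU982925
#III	75	Southern Ocean	T	C	T	A	T	G	C	T	2	1	KU982780-2830, KU982834, KU982884-90, KU982900-13, KU982915-16
#IV	6	Southern Ocean	T	G	T	A	T	T	C	A	2	2	KU982831-33, KU982934-36
#V	28	Southern Ocean	C	A	T	A	T	G	T	A	3	2	KU982835-58, KU982882, KU982917, KC754452-53
#VI	1	Southern Ocean	T	T	T	A	T	G	C	T	1	0	KU982914
#VII	1	Arctic Ocean	G	T	C	A	G	A	C	A	4	4	KU982926
#VIII	1	Arctic Ocean	T	A	T	A	T	G	T	C	1	0	KU982927
#IX	1	Arctic Ocean	T	G	T	G	T	G	C	C	3	1	KU982928
#X	5	Beagle Channel (Argentina)	C	A	T	G	T	G	C	C	3	1	KU982929-33
#XI	4	Canada (Pacific Ocean), California	G	G	C	G	A	G	C	A	6	4	CAISN1378-13, CAISN218-12, CAISN231-12, ZPC049-13
#XII	4	Canada (Hudson Bay), North Sea	C	T	T	G	T	T	C	G	3	2	CAISN326-12, KT208459, KT208745, MG316221
#XIII	20	Pacific Ocean (China, Korea and 1 N/A)	T	A	T	G	A	G	T	C	2	0	EU599542-44, JF269185-86, JN230859-71, KC287768, KR048987
#XIV	1	N/A (probably Korea)	C	A	T	G	A	A	T	C	2	1	KR048986
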