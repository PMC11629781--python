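# Study x taxon outcome records from the 30-study miniCOI performance
# review.  Misperformance rows (fail/bias), taxa, study codes and ocean
# basins are transcribed from the review's synthesis tables; the
# per-study primer-combination membership uses every study-code
# superscript printed in the per-combination synthesis plus its row
# counts (3 Leray-Folmer / 2 Leray-Meyer / 17 Leray-Geller / 4 Leray XT
# / 4 Other).  Remaining assignments (which unlisted studies used
# Leray-Geller, which scored the focal taxa NA vs OK, basins of studies
# with no misperformance entry) are SYNTHETIC: fixed arbitrarily but
# consistently with every published tally.  NA/OK rows are carried for
# the two focal taxa (Appendicularians, Oithona similis) only.
# outcome vocabulary: fail | bias | NA | OK.
# basin vocabulary: AO | PO | IO | ArO | SO | Undet.
study_code	taxon	taxon_group	ocean_basin	primer_combination	outcome
8	Oithona similis	copepod	AO	Leray–Folmer	fail
25	Oithona similis	copepod	AO	Other	bias
29	Oithona similis	copepod	AO	Leray–Meyer	bias
11	Oithona similis	copepod	PO	Leray–Folmer	fail
14	Oithona similis	copepod	PO	Leray–Geller	fail
15	Oithona similis	copepod	PO	Leray–Geller	fail
18	Oithona similis	copepod	PO	Leray–Geller	fail
19	Oithona similis	copepod	PO	Leray–Geller	fail
5	Oithona similis	copepod	Undet.	Leray–Geller	OK
13	Oithona similis	copepod	Undet.	Leray–Geller	OK
6	Oithona similis	copepod	AO	Leray XT	OK
9	Oithona similis	copepod	AO	Leray XT	OK
10	Oithona similis	copepod	AO	Leray XT	OK
27	Oithona similis	copepod	AO	Leray XT	OK
1	Oithona similis	copepod	Undet.	Leray–Folmer	NA
2	Oithona similis	copepod	PO	Leray–Geller	NA
3	Oithona similis	copepod	AO	Leray–Geller	NA
4	Oithona similis	copepod	Undet.	Other	NA
7	Oithona similis	copepod	SO	Other	NA
12	Oithona similis	copepod	PO	Leray–Geller	NA
16	Oithona similis	copepod	PO	Leray–Geller	NA
17	Oithona similis	copepod	PO	Leray–Geller	NA
20	Oithona similis	copepod	AO	Leray–Meyer	NA
21	Oithona similis	copepod	AO	Leray–Geller	NA
22	Oithona similis	copepod	Undet.	Leray–Geller	NA
23	Oithona similis	copepod	Undet.	Leray–Geller	NA
24	Oithona similis	copepod	ArO	Leray–Geller	NA
26	Oithona similis	copepod	Undet.	Leray–Geller	NA
28	Oithona similis	copepod	Undet.	Leray–Geller	NA
30	Oithona similis	copepod	Undet.	Other	NA
9	Acartia spp.	copepod	AO	Leray XT	bias
10	Acartia spp.	copepod	AO	Leray XT	bias
9	Acartia spp.	copepod	ArO	Leray XT	bias
11	Acartia spp.	copepod	PO	Leray–Folmer	bias
14	Acartia spp.	copepod	PO	Leray–Geller	bias
15	Acartia spp.	copepod	PO	Leray–Geller	bias
6	Microsetella norvegica	copepod	AO	Leray XT	bias
9	Microsetella norvegica	copepod	AO	Leray XT	bias
9	Microsetella norvegica	copepod	ArO	Leray XT	bias
30	Microsetella norvegica	copepod	Undet.	Other	fail
14	Paracalanus spp.	copepod	PO	Leray–Geller	bias
15	Paracalanus spp.	copepod	PO	Leray–Geller	bias
30	Calanus finmarchicus	copepod	Undet.	Other	fail
25	Calocalanus styliremis	copepod	AO	Other	fail
20	Centropages spp.	copepod	AO	Leray–Meyer	bias
12	Cyclopoida	copepod	PO	Leray–Geller	bias
10	Detrichocoryceaus spp.	copepod	AO	Leray XT	bias
9	Metridia spp.	copepod	AO	Leray XT	bias
9	Metridia spp.	copepod	ArO	Leray XT	bias
24	Microcalanus pygmaeus	copepod	ArO	Leray–Geller	fail
30	Oithona atlantica	copepod	Undet.	Other	fail
25	Oithona nana	copepod	AO	Other	fail
17	Oithonids	copepod	PO	Leray–Geller	fail
29	Oncaea spp.	copepod	AO	Leray–Meyer	bias
10	Oncaeidae	copepod	AO	Leray XT	bias
30	Pseudocalanus mimus	copepod	Undet.	Other	fail
20	Temora spp.	copepod	AO	Leray–Meyer	bias
3	Appendicularians	tunicate	AO	Leray–Geller	fail
8	Appendicularians	tunicate	AO	Leray–Folmer	fail
9	Appendicularians	tunicate	AO	Leray XT	fail
10	Appendicularians	tunicate	AO	Leray XT	fail
21	Appendicularians	tunicate	AO	Leray–Geller	bias
25	Appendicularians	tunicate	AO	Other	fail
27	Appendicularians	tunicate	AO	Leray XT	fail
29	Appendicularians	tunicate	AO	Leray–Meyer	fail
2	Appendicularians	tunicate	PO	Leray–Geller	fail
11	Appendicularians	tunicate	PO	Leray–Folmer	fail
14	Appendicularians	tunicate	PO	Leray–Geller	fail
15	Appendicularians	tunicate	PO	Leray–Geller	fail
17	Appendicularians	tunicate	PO	Leray–Geller	fail
18	Appendicularians	tunicate	PO	Leray–Geller	fail
19	Appendicularians	tunicate	PO	Leray–Geller	fail
9	Appendicularians	tunicate	ArO	Leray XT	fail
7	Appendicularians	tunicate	SO	Other	fail
30	Appendicularians	tunicate	Undet.	Other	fail
1	Appendicularians	tunicate	Undet.	Leray–Folmer	NA
4	Appendicularians	tunicate	Undet.	Other	NA
5	Appendicularians	tunicate	Undet.	Leray–Geller	NA
6	Appendicularians	tunicate	AO	Leray XT	NA
12	Appendicularians	tunicate	PO	Leray–Geller	NA
13	Appendicularians	tunicate	Undet.	Leray–Geller	NA
16	Appendicularians	tunicate	PO	Leray–Geller	NA
20	Appendicularians	tunicate	AO	Leray–Meyer	NA
22	Appendicularians	tunicate	Undet.	Leray–Geller	NA
23	Appendicularians	tunicate	Undet.	Leray–Geller	NA
24	Appendicularians	tunicate	ArO	Leray–Geller	NA
26	Appendicularians	tunicate	Undet.	Leray–Geller	NA
28	Appendicularians	tunicate	Undet.	Leray–Geller	NA
30	Oikopleura labradoriensis	tunicate	Undet.	Other	fail
3	Doliolida	tunicate	AO	Leray–Geller	fail
29	Doliolida	tunicate	AO	Leray–Meyer	fail
17	Doliolida	tunicate	PO	Leray–Geller	fail
18	Doliolida	tunicate	PO	Leray–Geller	fail
17	Pyrosomata	tunicate	PO	Leray–Geller	fail
18	Pyrosomata	tunicate	PO	Leray–Geller	fail
19	Pyrosomata	tunicate	PO	Leray–Geller	fail
3	Salpida	tunicate	AO	Leray–Geller	fail
18	Salpida	tunicate	PO	Leray–Geller	fail
19	Salpida	tunicate	PO	Leray–Geller	fail
14	Chaetognatha	other	PO	Leray–Geller	fail
16	Chaetognatha	other	PO	Leray–Geller	bias
2	Ctenophora	other	PO	Leray–Geller	fail
20	Mertensia spp.	other	AO	Leray–Meyer	fail
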