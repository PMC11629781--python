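# miniCOI primer registry: the forward/reverse primers and named
# combinations used across zooplankton COI metabarcoding studies.
# direction: forward|reverse; combination: name of the pair completed by
# this reverse primer (forward primers carry no combination).
name	direction	sequence	combination	forward_partner
mlCOIintF	forward	GGWACWGGWTGAACWGTWTAYCCYCC
HCO2198	reverse	TAAACTTCAGGGTGACCAAAAAATCA	Leray–Folmer	mlCOIintF
dgHCO2198	reverse	TAAACTTCAGGGTGACCAAARAAYCA	Leray–Meyer	mlCOIintF
jgHCO2198	reverse	TAIACYTCIGGRTGICCRAARAAYCA	Leray–Geller	mlCOIintF
mlCOIintF-XT	forward	GGWACWRGWTGRACWITITAYCCYCC
jgHCO2198	reverse	TAIACYTCIGGRTGICCRAARAAYCA	Leray XT	mlCOIintF-XT
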