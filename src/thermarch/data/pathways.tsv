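pathway_id	name	kos
WL	Wood-Ljungdahl pathway (CO2 fixation)	K00198,K05299,K15022,K01938
DSR	Dissimilatory sulfate reduction (sat-apr-dsr)	K00958,K00394,K00395,K11180,K11181
AMO	Ammonia oxidation (amoCAB)	K10944,K10945,K10946
MCR	Methyl-coenzyme M reductase (mcrABG)	K00399,K00401,K00402
ACS	Acetate oxidation (acetyl-CoA synthetase)	K01895
PTA_ACK	Phosphate acetyltransferase-acetate kinase acetogenesis	K00625,K00925
HYD3B	NADP-coupled group 3b NiFe hydrogenase	K18016,K18017,K18018
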