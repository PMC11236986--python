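# Curated pan-assay interference (PAINS) family patterns, one per line:
# SMARTS<TAB>id. A compact selection of the classic promiscuous-binder
# families (quinones, catechols, rhodanines, hydrazones, azo dyes, Michael
# acceptors) written for this package; any external SMARTS file in the same
# format may be supplied instead.
O=C1C=CC(=O)C=C1	quinone_para
O=C1C(=O)C=CC=C1	quinone_ortho
Oc1ccccc1O	catechol
O=C1CSC(=S)N1	rhodanine
O=C1CSC(=N)N1	pseudo_rhodanine
S=C1NC(=O)c2ccccc21	thioxo_oxindole
Oc1ccccc1C=NN	hzone_phenol
Oc1ccc(C=NN)cc1	hzone_phenol_para
cN=Nc	azo_aromatic
O=C1C=CSN1	isothiazolone
O=C1NC(=O)NC(=O)C1=C	ene_barbiturate
NC(=S)N	thiourea
C=CC=CC=CC=C	polyene_tetra
O=C1C=C(O)C=CC1=O	hydroxy_quinone
S=C1NC(=S)NC1=O	thio_hydantoin
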