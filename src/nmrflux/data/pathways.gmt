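tca_cycle	na	citrate	succinate	malate	glutamine
glutathione_metabolism	na	gsh	gssg	5-oxoproline	glycine	glutamine
amino_acid_metabolism	na	alanine	glycine	threonine	methionine	tryptophan	homoserine	glutamine
glycolysis_gluconeogenesis	na	glucose	lactate	glycerol	alanine
membrane_and_lipid	na	choline	myo-inositol	carnitine	glycerol	creatine
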