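# NRP mass-conversion table, v1 (best-effort reconstruction).
# Monoisotopic residue masses (Da) for proteinogenic and common
# nonproteinogenic NRP monomers; candidates sharing one row are
# isobaric at any tolerance. Columns: mass<TAB>candidates<TAB>label.
57.02146	gly	glycine
71.03711	ala	alanine
85.05276	abu	2-aminobutyric acid
85.08915	vol	valinol (chain-terminating)
87.03203	ser	serine
97.05276	pro	proline
99.06841	val/iva	valine / isovaline (isomers)
100.06366	dab	2,4-diaminobutyric acid
101.04768	thr/allothr	threonine / allo-threonine (isomers)
103.00919	cys	cysteine
111.06841	pip	pipecolic acid (isomer of Pro+CH2)
113.08406	ile/leu	isoleucine / leucine (isomers)
114.04293	asn	asparagine
114.07931	orn	ornithine
115.02694	asp	aspartate
120.02113	sal	salicylate (aryl-acid starter)
128.05858	gln	glutamine
128.09496	lys	lysine
129.04259	glu	glutamate
131.04049	met	methionine
136.01604	dhb	2,3-dihydroxybenzoate (aryl-acid starter)
137.05891	his	histidine
143.05824	aad	2-aminoadipic acid
147.06841	phe	phenylalanine
149.04768	hpg	4-hydroxyphenylglycine
156.10111	arg	arginine
157.08513	cit	citrulline
163.06333	tyr	tyrosine
165.04260	dhpg	3,5-dihydroxyphenylglycine
177.07898	hty	homotyrosine
179.05824	bht	beta-hydroxytyrosine
186.07931	trp	tryptophan
190.07423	kyn	kynurenine
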