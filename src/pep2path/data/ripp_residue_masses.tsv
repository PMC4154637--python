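# RiPP mass-conversion table, v1 (best-effort reconstruction).
# Maps MS/MS mass shifts to the GENOME-ENCODED residues they may
# represent, including post-translational degeneracies common in RiPPs:
# a dehydrated Ser/Thr (Dha/Dhb) appears 18.011 Da light, and residues
# engaged in thioether crosslinks can read at Ala- or Ser-like masses
# while being encoded as Cys. Ile/Leu are strictly isobaric; Gln/Lys
# merge only at tolerances above 0.037 Da.
# Columns: mass<TAB>candidates<TAB>label.
57.02146	gly	glycine
69.02146	ser	dehydroalanine (Ser -H2O)
71.03711	ala/cys	alanine, or thioether-bridged Cys reading at Ala mass
83.03711	thr	dehydrobutyrine (Thr -H2O)
87.03203	ser/cys	serine, or modified Cys reading at Ser mass
97.05276	pro	proline
99.06841	val	valine
101.04768	thr	threonine
103.00919	cys	cysteine
113.08406	ile/leu	isoleucine / leucine (isomers)
114.04293	asn	asparagine
115.02694	asp	aspartate
128.05858	gln	glutamine
128.09496	lys	lysine
129.04259	glu	glutamate
131.04049	met	methionine
137.05891	his	histidine
147.06841	phe	phenylalanine
156.10111	arg	arginine
163.06333	tyr	tyrosine
186.07931	trp	tryptophan
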