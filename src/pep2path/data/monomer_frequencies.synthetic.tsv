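# SYNTHETIC monomer-frequency snapshot, v1.
# Hand-set counts shaped like the monomer abundances seen in known
# nonribosomal peptides (NORINE-style background); NOT a database export.
# alphabet: aad/abu/ala/allothr/arg/asn/asp/bht/cit/cys/dab/dhb/dhpg/gln/glu/gly/his/hpg/hty/ile/iva/kyn/leu/lys/met/orn/phe/pip/pro/sal/ser/thr/trp/tyr/val/vol
# pseudocount: 1
ala	420
gly	340
leu	380
ser	310
thr	300
val	290
asp	260
pro	240
glu	230
phe	160
ile	150
tyr	140
orn	130
asn	120
gln	110
lys	100
arg	90
dab	85
dhb	70
hpg	65
his	60
cys	55
abu	55
trp	45
dhpg	45
met	40
pip	40
bht	35
iva	30
sal	30
aad	25
hty	20
allothr	18
cit	15
vol	12
kyn	10
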