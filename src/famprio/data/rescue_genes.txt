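# Example cancer-gene rescue list (oncogenes, tumor suppressors and
# autosomal-dominant familial syndrome genes). Illustrative fixture;
# supply your own curated list in production.
APC
ATM
BRCA1
BRCA2
CDKN2A
CHEK2
MLH1
MSH2
PALB2
POT1
PTEN
RET
TP53
VHL
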