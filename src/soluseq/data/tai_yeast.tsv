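codon	tai
AAA	0.431034
AAC	0.615764
AAG	1.000000
AAT	0.363300
ACA	0.246373
ACC	0.487685
ACG	0.140394
ACT	0.677340
AGA	0.677340
AGC	0.246305
AGG	0.278325
AGT	0.145320
ATA	0.123153
ATC	0.576355
ATG	0.307882
ATT	0.800493
CAA	0.554187
CAC	0.431034
CAG	0.238916
CAT	0.254310
CCA	0.615776
CCC	0.088670
CCG	0.197044
CCT	0.123153
CGA	0.000037
CGC	0.266010
CGG	0.061576
CGT	0.369458
CTA	0.184729
CTC	0.061576
CTG	0.059113
CTT	0.036330
GAA	0.862069
GAC	0.985222
GAG	0.399015
GAT	0.581281
GCA	0.307950
GCC	0.487685
GCG	0.098522
GCT	0.677340
GGA	0.184729
GGC	0.985222
GGG	0.182266
GGT	0.581281
GTA	0.123239
GTC	0.620690
GTG	0.100985
GTT	0.862069
TAC	0.492611
TAT	0.290640
TCA	0.184797
TCC	0.487685
TCG	0.120690
TCT	0.677340
TGC	0.246305
TGG	0.369458
TGT	0.145320
TTA	0.431034
TTC	0.615764
TTG	0.753695
TTT	0.363300
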