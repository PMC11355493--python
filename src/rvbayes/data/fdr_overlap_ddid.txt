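# Genes nominated at Bayesian FDR < 5% that are also on the 299-gene DD/ID list
ZMYM2
SHANK3
STAG1
GRIN2A
ZMYND11
KDM6B
PCDH19
HIVEP2
TRIO
ASH1L
SETD1A
SRRM2
CACNA1G
PPP2R1A
BMPR2
CLTC
ADCY5
CACNA1C
SATB1
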