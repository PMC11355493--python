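# Genes nominated at Bayesian FDR < 5% that are also on the 102-gene autism list
ITSN1
DSCAM
ZMYM2
SHANK3
FAM120A
ZMYND11
KDM6B
ANK2
ASH1L
CAMTA2
NRXN1
ADCY5
PSMD11
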