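# Genes nominated at Bayesian FDR < 5% that are also on the 64-gene SCZ GWAS list
SP4
GRIN2A
CACNA1C
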