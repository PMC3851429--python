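# Eight key multiple-myeloma genes (custom MM gene list)
CCND1
CCND3
DKK1
FGFR3
MAF
MAFB
NFKB1
WHSC1
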