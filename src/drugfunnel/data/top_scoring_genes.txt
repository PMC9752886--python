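CDKN2A
CTNNB1
BRCA2
AR
CCND2
PML
MYC
CCND3
STAT3
ZBTB16
EGFR
ESR1
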