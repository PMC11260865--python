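# Drugged targets also associated with blood pressure / hypertension traits,
# transcribed verbatim from the printed gene list (including the printed
# spelling "TNSFSF12"; the packaged manual symbol map resolves it to TNFSF12).
ADRB1
ENPEP
EPHA3
FGFR1
HBEGF
HCN4
IL6R
KCNH2
KCNJ5
MAPT
MC4R
MET
MYH6
MYL4
NDUFAF3
NDUFB10
NPR3
PDE3A
PDE4B
PRKCA
PSMB7
PTK2
SCN5A
SRD5A3
THRB
TNSFSF12
TNFSF13
TNNT3
TUBB3
WT1
XPO1
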