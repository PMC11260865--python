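# Drug-associated targets absent from the druggable-genome list,
# transcribed verbatim from the printed gene list.
FDPS
TNNT3
AOPEP
NDUFAF3
MET
RPS2
RAF1
WT1
RPL32
MYH7
MYH6
POLR2A
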