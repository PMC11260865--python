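# Curated reported-label -> approved-symbol corrections (web-search stage).
C9orf3	AOPEP
NRC31	NR3C1
TNSFSF12	TNFSF12
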