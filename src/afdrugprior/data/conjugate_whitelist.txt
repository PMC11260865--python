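# Conjugates of two active moieties that remain unique drugs (never
# collapsed by salt-token stripping), e.g. antibody-drug conjugates.
trastuzumab emtansine
trastuzumab deruxtecan
gemtuzumab ozogamicin
brentuximab vedotin
inotuzumab ozogamicin
polatuzumab vedotin
enfortumab vedotin
sacituzumab govitecan
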