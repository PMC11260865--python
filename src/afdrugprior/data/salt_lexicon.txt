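# Trailing salt / ester / counter-ion tokens stripped during drug
# deduplication (case-insensitive, applied repeatedly from the end of
# the name). One token per line; multi-word tokens allowed.
hydrochloride
dihydrochloride
hydrobromide
bromide
chloride
iodide
tartrate
bitartrate
succinate
fumarate
maleate
malate
mesylate
mesilate
besylate
besilate
tosylate
edisylate
camsylate
oxalate
citrate
lactate
gluconate
stearate
palmitate
valerate
propionate
dipropionate
acetate
acetonide
butyrate
phosphate
diphosphate
hydrogen tartrate
sulfate
sulphate
bisulfate
nitrate
pamoate
embonate
pivalate
enanthate
decanoate
undecanoate
benzoate
salicylate
sodium
disodium
potassium
calcium
magnesium
zinc
lysine
meglumine
hemihydrate
monohydrate
dihydrate
trihydrate
hydrate
anhydrous
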