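region	roi
precentral	motor
paracentral	motor
superiorfrontal	frontal
rostralmiddlefrontal	frontal
caudalmiddlefrontal	frontal
parsopercularis	frontal
parstriangularis	frontal
parsorbitalis	frontal
lateralorbitofrontal	frontal
medialorbitofrontal	frontal
frontalpole	frontal
superiorparietal	parietal
inferiorparietal	parietal
supramarginal	parietal
postcentral	parietal
precuneus	parietal
superiortemporal	temporal
middletemporal	temporal
inferiortemporal	temporal
bankssts	temporal
fusiform	temporal
transversetemporal	temporal
entorhinal	temporal
temporalpole	temporal
parahippocampal	temporal
insula	none
rostralanteriorcingulate	none
caudalanteriorcingulate	none
posteriorcingulate	none
isthmuscingulate	none
lateraloccipital	none
lingual	none
cuneus	none
pericalcarine	none
unknown	none
corpuscallosum	none
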