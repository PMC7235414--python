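# Mapping of DKT cortical labels (plus subcortical structures) to the
# "motor-learning network": frontal, cingulate and parietal cortices,
# the striatum, the hippocampus and the cerebellum.
version: 1
frontal:
  - caudalmiddlefrontal
  - frontalpole
  - lateralorbitofrontal
  - medialorbitofrontal
  - paracentral
  - parsopercularis
  - parsorbitalis
  - parstriangularis
  - precentral
  - rostralmiddlefrontal
  - superiorfrontal
cingulate:
  - caudalanteriorcingulate
  - isthmuscingulate
  - posteriorcingulate
  - rostralanteriorcingulate
parietal:
  - inferiorparietal
  - postcentral
  - precuneus
  - superiorparietal
  - supramarginal
striatum:
  - accumbens
  - caudate
  - putamen
hippocampus:
  - hippocampus
cerebellum:
  - cerebellum-cortex
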