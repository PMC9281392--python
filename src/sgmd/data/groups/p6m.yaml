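name: p6m
hermann_mauguin: p6mm
dimension: 2
bravais_class: hexagonal
multiplicity: 12
generators: ["x-y,x", "-y,-x"]
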