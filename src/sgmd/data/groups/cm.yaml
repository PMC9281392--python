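name: cm
hermann_mauguin: c1m1
dimension: 2
bravais_class: centered-rectangular
multiplicity: 4
generators: ["-x,y", "x+1/2,y+1/2"]
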