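name: pg
hermann_mauguin: p1g1
dimension: 2
bravais_class: rectangular
multiplicity: 2
generators: ["-x,y+1/2"]
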