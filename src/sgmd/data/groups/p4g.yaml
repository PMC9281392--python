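name: p4g
hermann_mauguin: p4gm
dimension: 2
bravais_class: square
multiplicity: 8
generators: ["-y,x", "-x+1/2,y+1/2"]
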