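name: p4m
hermann_mauguin: p4mm
dimension: 2
bravais_class: square
multiplicity: 8
generators: ["-y,x", "-x,y"]
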