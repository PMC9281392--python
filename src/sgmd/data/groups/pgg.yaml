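name: pgg
hermann_mauguin: p2gg
dimension: 2
bravais_class: rectangular
multiplicity: 4
generators: ["-x,-y", "x+1/2,-y+1/2"]
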