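name: pm
hermann_mauguin: p1m1
dimension: 2
bravais_class: rectangular
multiplicity: 2
generators: ["-x,y"]
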