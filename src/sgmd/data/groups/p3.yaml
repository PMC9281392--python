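name: p3
dimension: 2
bravais_class: hexagonal
multiplicity: 3
generators: ["-y,x-y"]
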