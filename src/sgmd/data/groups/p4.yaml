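name: p4
dimension: 2
bravais_class: square
multiplicity: 4
generators: ["-y,x"]
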