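name: p1
dimension: 2
bravais_class: oblique
multiplicity: 1
generators: []
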