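name: P1
number: 1
dimension: 3
bravais_class: triclinic
multiplicity: 1
generators: []
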