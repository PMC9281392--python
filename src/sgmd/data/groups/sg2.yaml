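name: P-1
number: 2
dimension: 3
bravais_class: triclinic
multiplicity: 2
generators: ["-x,-y,-z"]
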