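name: P4/mbm
number: 127
dimension: 3
bravais_class: tetragonal
multiplicity: 16
generators: ["-y,x,z", "-x,-y,-z", "x+1/2,-y+1/2,z"]
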