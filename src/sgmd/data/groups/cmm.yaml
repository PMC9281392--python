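name: cmm
hermann_mauguin: c2mm
dimension: 2
bravais_class: centered-rectangular
multiplicity: 8
generators: ["-x,-y", "-x,y", "x+1/2,y+1/2"]
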