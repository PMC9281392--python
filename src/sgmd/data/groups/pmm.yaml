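name: pmm
hermann_mauguin: p2mm
dimension: 2
bravais_class: rectangular
multiplicity: 4
generators: ["-x,-y", "-x,y"]
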