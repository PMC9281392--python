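name: p2
dimension: 2
bravais_class: oblique
multiplicity: 2
generators: ["-x,-y"]
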