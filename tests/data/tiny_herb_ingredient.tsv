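H1	i1
H1	i2
H1	i3
H2	i4
H2	i5
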