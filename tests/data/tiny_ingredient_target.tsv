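i1	P1
i1	P2
i2	P2
i3	P3
i4	P1
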