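TERM_A	synthetic fixture	g1	g2	g3
TERM_B	synthetic fixture	g3	g4	g5	g6
cancer pathway	synthetic fixture	g1	g5
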