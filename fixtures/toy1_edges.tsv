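node_a	node_b	cost
A	B	0.2
B	C	0.3
C	D	0.8
D	E	0.2
E	F	0.4
B	E	0.9
A	C	0.6
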