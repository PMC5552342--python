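node_a	node_b	cost
A1	A2	0.1
A2	A3	0.1
B1	B2	0.1
B2	B3	0.1
A3	B1	1.5
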