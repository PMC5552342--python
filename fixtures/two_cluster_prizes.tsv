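node	prize
A1	3
A2	3
A3	3
B1	3
B2	3
B3	3
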