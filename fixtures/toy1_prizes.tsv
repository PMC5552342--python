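node	prize
A	3
D	2.5
F	1.5
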