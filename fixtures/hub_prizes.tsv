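node	prize
A1	5
A2	5
A3	5
T01	0.5
T02	0.5
T03	0.5
T04	0.5
T05	0.5
T06	0.5
T07	0.5
T08	0.5
T09	0.5
T10	0.5
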