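node_a	node_b	cost
A1	A2	0.2
A2	A3	0.2
A1	X	0.1
X	T01	0.1
X	T02	0.1
X	T03	0.1
X	T04	0.1
X	T05	0.1
X	T06	0.1
X	T07	0.1
X	T08	0.1
X	T09	0.1
X	T10	0.1
T01	D01	0.9
T01	D02	0.9
T01	D03	0.9
T01	D04	0.9
T01	D05	0.9
T01	D06	0.9
T01	D07	0.9
T01	D08	0.9
T01	D09	0.9
T01	D10	0.9
T02	D01	0.9
T02	D02	0.9
T02	D03	0.9
T02	D04	0.9
T02	D05	0.9
T02	D06	0.9
T02	D07	0.9
T02	D08	0.9
T02	D09	0.9
T02	D10	0.9
T03	D01	0.9
T03	D02	0.9
T03	D03	0.9
T03	D04	0.9
T03	D05	0.9
T03	D06	0.9
T03	D07	0.9
T03	D08	0.9
T03	D09	0.9
T03	D10	0.9
T04	D01	0.9
T04	D02	0.9
T04	D03	0.9
T04	D04	0.9
T04	D05	0.9
T04	D06	0.9
T04	D07	0.9
T04	D08	0.9
T04	D09	0.9
T04	D10	0.9
T05	D01	0.9
T05	D02	0.9
T05	D03	0.9
T05	D04	0.9
T05	D05	0.9
T05	D06	0.9
T05	D07	0.9
T05	D08	0.9
T05	D09	0.9
T05	D10	0.9
T06	D01	0.9
T06	D02	0.9
T06	D03	0.9
T06	D04	0.9
T06	D05	0.9
T06	D06	0.9
T06	D07	0.9
T06	D08	0.9
T06	D09	0.9
T06	D10	0.9
T07	D01	0.9
T07	D02	0.9
T07	D03	0.9
T07	D04	0.9
T07	D05	0.9
T07	D06	0.9
T07	D07	0.9
T07	D08	0.9
T07	D09	0.9
T07	D10	0.9
T08	D01	0.9
T08	D02	0.9
T08	D03	0.9
T08	D04	0.9
T08	D05	0.9
T08	D06	0.9
T08	D07	0.9
T08	D08	0.9
T08	D09	0.9
T08	D10	0.9
T09	D01	0.9
T09	D02	0.9
T09	D03	0.9
T09	D04	0.9
T09	D05	0.9
T09	D06	0.9
T09	D07	0.9
T09	D08	0.9
T09	D09	0.9
T09	D10	0.9
T10	D01	0.9
T10	D02	0.9
T10	D03	0.9
T10	D04	0.9
T10	D05	0.9
T10	D06	0.9
T10	D07	0.9
T10	D08	0.9
T10	D09	0.9
T10	D10	0.9
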