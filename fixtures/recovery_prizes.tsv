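node	prize
N005	8.08067
N015	0.116878
N028	7.16693
N044	0.408297
N051	7.60326
N067	2.39316
N082	4.03045
N083	2.00722
N098	5.44893
N099	0.824339
N111	0.368093
N136	0.799154
N144	3.7958
N160	3.68526
N172	0.623869
N183	0.440303
N215	1.95893
N231	3.90766
N257	0.136936
N258	2.70701
N294	11.4824
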