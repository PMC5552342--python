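N005
N028
N051
N067
N082
N083
N098
N136
N144
N160
N172
N215
N231
N258
N294
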