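,condition
S0000,C1
S0001,C0
S0002,C1
S0003,C1
S0004,C1
S0005,C1
S0006,C0
S0007,C1
S0008,C0
S0009,C0
S0010,C0
S0011,C1
S0012,C0
S0013,C0
S0014,C0
S0015,C0
S0016,C1
S0017,C1
S0018,C0
S0019,C0
S0020,C1
S0021,C0
S0022,C1
S0023,C1
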