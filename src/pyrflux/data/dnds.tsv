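activity	omega
CPSase	0.01
ATCase	0.02
URA4	0.14
URA1	0.05
URA5	0.14
URA3	0.04
URA6	0.11
URA7	0.05
YNK1	0.05
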