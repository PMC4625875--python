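species	target_uM	sigma_uM
ump	0.37	2.5
udp	2.9	2.5
utp	6.7	2.5
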