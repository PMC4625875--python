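metabolite	model_concentration_mM	experimental_concentration_mM
ump	4.2e-4	3.7e-4
udp	2.9e-3	2.9e-3
utp	6.7e-3	6.7e-3
ctp	7.5e-1
cp	2.7e-1
ca	4.7e-3
dho	1.8e-5
oro	2.2e-6
omp	5.8e-2
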