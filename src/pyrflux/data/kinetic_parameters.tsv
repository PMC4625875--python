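parameter	description	initial_value	optimized_value	sensitivity	activity	prior_class	unit
vmax1	Vmax for carbamoyl phosphate synthetase	5.40e-1	3.62	9.68e-1	CPSase	measured	mM/hr
K_utp	UTP binding constant	1.40	1.41	5.49e-3	CPSase	measured	mM
K_atp	ATP binding constant	7.50	1.29	-8.68e-1	CPSase	measured	mM
K_q	Km for glutamine	7.00e-2	5.78e-2	-9.32e-2	CPSase	measured	mM
K_bc	Km for bicarbonate	8.00	2.37	-5.96e-1	CPSase	measured	mM
vmax2	Vmax for aspartate transcarbamylase	1.10	2.45	2.00e-1	ATCase	measured	mM/hr
K_asp	Km for aspartate	2.80e-1	1.68e-1	-1.24e-1	ATCase	measured	mM
K_m2	Km for carbamoyl phosphate (ATCase)	4.00	2.00	-1.77e-1	ATCase	measured	mM
vmax3	Vmax for dihydroorotase	2.47e1	2.87e1	1.21e-4	URA4	reference	mM/hr
K_m3	Km for dihydroorotase	7.00e-1	1.27	-1.20e-4	URA4	reference	mM
vmax4	Vmax for dihydroorotate dehydrogenase	9.18e1	9.18e1	1.73e-5	URA1	measured	mM/hr
K_m4	Km for dihydroorotate dehydrogenase	1.60e-2	1.60e-2	-1.73e-5	URA1	measured	mM
vmax5	Vmax for orotate phosphoribosyltransferase	5.18e3	5.23e3	2.10e-5	URA5	measured	mM/hr
K_m5	Km for orotate phosphoribosyltransferase	1.97e-2	1.95e-2	-2.10e-5	URA5	measured	mM
vmax6	Vmax for OMP decarboxylase	3.03e1	3.50e1	4.63e-2	URA3	measured	mM/hr
K_m6	Km for OMP decarboxylase	3.20e1	2.03e1	-4.62e-2	URA3	reference	mM
vmax7	Vmax for nucleoside diphosphate kinase	6.48	5.83	-6.92e-5	YNK1	measured	mM/hr
K_m7	Km for nucleoside diphosphate kinase	1.50e-1	1.66e-1	6.79e-5	YNK1	measured	mM
vmax8	Vmax for CTP synthase	5.40	1.63e-1	2.46e-2	URA7	measured	mM/hr
K_m8	Km for CTP synthase	7.40e-4	4.36e-3	-5.22e-3	URA7	measured	mM
vmax10	Vmax for UMP kinase	1.14	6.56	-1.02	URA6	measured	mM/hr
K_m10	Km for UMP kinase	1.50e-1	2.68e-2	1.00	URA6	measured	mM
g_pyr	Pyrimidine utilization rate	4.00e-1	1.98e-1	1.16e-4	-	reference	mM/hr
K_Mp	Km for pyrimidine utilization	5.80	5.49	-1.16e-4	-	reference	mM
bc	Intracellular bicarbonate conc.	4.51e-1	1.52	5.96e-1	-	measured	mM
glu	Intracellular glutamine conc.	4.51e-1	5.46e-1	9.32e-2	-	measured	mM
asp	Intracellular aspartate conc.	5.85e-2	9.73e-2	1.24e-1	-	measured	mM
atp	Initial ATP conc.	2.59e-2	1.51e-1	8.68e-1	-	measured	mM
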