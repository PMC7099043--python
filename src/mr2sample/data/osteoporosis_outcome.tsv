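snp_id	chromosome	position	effect_allele	eaf	beta	se	pvalue
rs7577696	2	32278782	G	0.49381	8.71E-05	6.15E-05	1.57E-01
rs6760105	2	32307386	G	0.491214	8.63E-05	6.15E-05	1.61E-01
rs6748621	2	32262201	C	0.495208	1.01E-04	6.17E-05	1.03E-01
rs2300702	2	31788018	C	0.545527	-9.89E-05	6.11E-05	1.06E-01
rs2268797	2	31783752	C	0.552716	-9.53E-05	6.11E-05	1.18E-01
rs2250417	2	32412832	T	0.304113	-3.32E-05	6.01E-05	5.81E-01
rs212745	2	32457537	C	0.480232	-9.38E-05	6.16E-05	1.28E-01
rs212713	11	112085316	C	0.494409	-9.82E-05	6.00E-05	1.02E-01
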