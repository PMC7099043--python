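snp_id	chromosome	position	effect_allele	eaf	beta	se
rs7577696	2	32278782	G	0.49381	0.08	0.01
rs6760105	2	32307386	G	0.491214	0.06	0.01
rs6748621	2	32262201	C	0.495208	0.08	0.01
rs2300702	2	31788018	C	0.545527	0.07	0.01
rs2268797	2	31783752	C	0.552716	0.07	0.01
rs2250417	2	32412832	T	0.304113	0.1	0.01
rs212745	2	32457537	C	0.480232	0.07	0.01
rs212713	11	112085316	C	0.494409	0.06	0.01
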