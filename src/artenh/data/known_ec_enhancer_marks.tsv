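# 32 published in vivo-validated endothelial enhancers with their
# enhancer-mark evidence across five datasets (two human, three mouse).
# Coordinates are 1-based fully-closed as printed in genome browsers.
# Mark values: yes / no; "yes*" marks signal that extends to many
# non-endothelial cell types (counts as evidence, flagged non-specific).
# arterial = 1 for the eight previously published arterial enhancers.
name	arterial	hg19_seq	hg19_start	hg19_end	mm9_seq	mm9_start	mm9_end	h_dnase	h_histone	m_artery_atac	m_retina_atac	m_e11_p300
Apln+28	0	chrX	128756756	128757160	chrX	45359306	45359632	yes	yes	no	yes	yes
Dab2-240	0	chr5	39755997	39756596	chr15	6009719	6010138	yes*	yes	no	no	yes
Dll4in3	1	chr15	41222881	41223570	chr2	119152838	119153684	yes	yes	yes	yes	yes
Dll4-12	1	chr15	41210706	41211825	chr2	119140274	119141353	yes	yes	yes	yes	yes
Ece1in1	1	chr1	21606038	21607057	chr4	137475719	137476738	yes	yes	yes	yes	yes
Egfl7-9	0	chr9	139540750	139541299	chr2	26427513	26427707	yes	yes	yes	yes	yes
Egfl7-2	0	chr9	139550292	139550891	chr2	26434087	26434301	yes	yes	yes	yes	yes
Emcn-22	0	chr4	101460885	101461224	chr3	136984547	136984951	no	yes	yes	no	no
Eng-8	0	chr9	130624538	130624804	chr2	32493606	32493823	yes	yes	yes	yes	yes
Eng+9	0	chr9	130607199	130607657	chr2	32511282	32511641	yes	yes	yes	yes	yes
Ephb4-2	0	chr7	100426337	100427259	chr5	137789910	137790581	yes	yes	no	no	yes
Fli1+12	0	chr11	128575436	128575782	chr9	32337295	32337538	yes	yes	yes	yes	yes
Flk1+3	0	chr4	55987345	55987920	chr5	76370627	76371056	yes	yes	no	no	yes
Flk1in10	1	chr4	55972978	55973903	chr5	76357891	76358715	yes	no	no	yes	yes
Flt4+26	0	chr5	180050291	180050684	chr11	49445777	49446175	no	yes	yes	yes	yes
Foxp1+138	0	chr3	71493515	71493886	chr6	99338958	99339515	yes	yes	no	yes	yes
Gata2+9	0	chr3	128201971	128202273	chr6	88153077	88153386	yes	yes	yes	yes	yes
Hey1-18	1	chr8	80695610	80697109	chr3	8685099	8685821	yes	yes	yes	yes	yes
Hlx-3	0	chr1	221049978	221050354	chr1	186558918	186559303	yes	yes	yes	yes	yes
Mef2F10	0	chr5	88110980	88111253	chr13	83721761	83722057	yes	yes	no	yes	yes
Mef2F7	0	chr5	88123031	88123357	chr13	83711180	83711509	yes	yes	yes	yes	yes
Notch1+16	1	chr9	139424543	139424953	chr2	26346100	26346671	yes	yes	yes	yes	yes
Notch1+33	0	chr9	139406356	139406655	chr2	26330559	26330785	yes	yes	yes	yes	yes
CoupTFII-965	0	chr15	95908708	95909240	chr7	78456407	78456767	yes	yes	yes	yes	yes
Nrp1+28	0	chr10	33590960	33591499	chr8	130911132	130911551	no	yes	yes	yes	yes
Nrp2+26	0	chr2	206573202	206573523	chr1	62776231	62776553	yes	yes	yes	yes	yes
Pdgfrb+18	0	chr5	149516883	149517356	chr18	61219244	61219566	no	yes	no	no	no
Epcr-5	0	chr20	33754176	33754585	chr2	155568588	155569127	yes	yes	yes	no	yes
Sema6d-55	1	chr15	47958023	47958764	chr2	124380522	124381285	yes	yes	yes	yes	yes
Sox7+14	1	chr8	10573085	10574291	chr14	64576271	64577533	yes	yes	yes	yes	yes
Tal1+19	0	chr1	47677539	47677958	chr4	114748131	114748530	yes	yes	yes	yes	yes
Tal1-4	0	chr1	47701050	47701347	chr4	114725243	114725552	no	yes	yes	yes	yes
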