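# Mosaic Tol2 transgenic zebrafish screen of putative arterial enhancers
# plus the eight previously published arterial enhancers (published = 1,
# assayed in earlier studies, no injection counts here). n_injected /
# n_gfp_positive are blank where no counts were reported. weak_flag = 1
# marks enhancers whose GFP was weak and/or limited to a small number of
# endothelial cells. in_vivo_class uses the controlled vocabulary
# {arterial, pan_EC, venous, weak, inactive}; in_silico_label is the
# published HUVEC-vs-HUAEC chromatin-state designation, verbatim.
name	gene	n_injected	n_gfp_positive	weak_flag	in_vivo_class	in_silico_label	published
Cxcr4-232	Cxcr4	163	0	0	inactive	Uncalled	0
Cxcr4-194	Cxcr4	46	25	0	arterial	Uncalled	0
Cxcr4-130	Cxcr4	95	0	0	inactive	Uncalled	0
Cxcr4-117	Cxcr4	209	9	1	inactive	Uncalled	0
hCxcr4-117/CXCR4-125	Cxcr4	81	0	0	inactive	Uncalled	0
Cxcr4-113	Cxcr4	300	0	0	inactive	Common EC enhancer	0
Cxcr4-109	Cxcr4	89	0	0	inactive	Common EC enhancer	0
Cxcr4+1	Cxcr4	33	0	0	inactive	Uncalled	0
Cxcr4+119	Cxcr4	187	0	0	inactive	Arterial enhancer	0
Cxcr4+135	Cxcr4	69	56	0	arterial	Uncalled	0
Cxcr4+151	Cxcr4	96	50	0	arterial	Arterial TSS	0
Efnb2-333	Efnb2	152	93	0	arterial	Common EC enhancer	0
Efnb2-159	Efnb2	247	217	0	arterial	Common EC enhancer	0
Efnb2-141	Efnb2	74	36	0	arterial	Arterial TSS	0
Efnb2-112	Efnb2	65	30	0	arterial	Arterial TSS	0
Efnb2+3	Efnb2	92	0	0	inactive	Common EC TSS	0
Efnb2+37	Efnb2	114	18	1	weak	Common EC enhancer	0
Efnb2+172	Efnb2	63	0	0	inactive	Common EC enhancer	0
Efnb2+209	Efnb2	158	0	0	inactive	Common EC enhancer	0
Gja4+24	Gja4	52	0	0	inactive	Uncalled	0
Gja4+50	Gja4	232	187	0	arterial	Common EC enhancer	0
Gja4+57	Gja4	192	0	0	inactive	Uncalled	0
Unc5b-57	Unc5b	50	21	0	venous	Uncalled	0
Unc5b+14	Unc5b	61	0	0	inactive	Uncalled	0
Unc5b+23	Unc5b	82	16	1	weak	Arterial enhancer	0
Unc5b+30	Unc5b	96	79	0	arterial	Arterial enhancer	0
Unc5b+39	Unc5b	96	56	0	arterial	Arterial enhancer	0
Unc5b+43	Unc5b	111	0	0	inactive	Arterial enhancer	0
Acvrl1-5	Acvrl1			0	inactive	Common EC enhancer	0
Acvrl1-1/p	Acvrl1			0	inactive	Common EC TSS	0
Acvrl1+6	Acvrl1	127	49	0	arterial	Common EC TSS	0
Acvrl1+16	Acvrl1	205	0	0	inactive	Common EC TSS	0
Acvrl1+19	Acvrl1	95	0	0	inactive	Common EC TSS	0
Cxcl12-184	Cxcl12	64	0	0	inactive	Common EC enhancer	0
Cxcl12-2	Cxcl12	32	0	0	inactive	Common EC enhancer	0
Cxcl12+239	Cxcl12	70	1	0	inactive	Uncalled	0
Cxcl12+265	Cxcl12	42	1	0	inactive	Uncalled	0
Cxcl12+269	Cxcl12	163	63	0	arterial	Uncalled	0
Cxcl12+298	Cxcl12	51	0	0	inactive	Common EC enhancer	0
Cxcl12+376	Cxcl12	149	0	0	inactive	Uncalled	0
Cxcl12+383	Cxcl12	152	37	1	weak	Uncalled	0
Cxcl12+439	Cxcl12	73	0	0	inactive	Common EC enhancer	0
Cxcl12+445	Cxcl12	145	0	0	inactive	Common EC TSS	0
Gja5-7	Gja5	66	39	0	arterial	Arterial enhancer	0
Gja5-21	Gja5	38	0	0	inactive	Common EC enhancer	0
Gja5-28	Gja5	156	0	0	inactive	Uncalled	0
Gja5-78	Gja5	76	62	0	arterial	Common EC enhancer	0
Gja5-93	Gja5	253	0	0	inactive	Arterial enhancer	0
Nrp1+28	Nrp1			0	pan_EC	Common EC enhancer	0
Nrp1+76	Nrp1	54	0	0	inactive	Common EC enhancer	0
Nrp1+78	Nrp1	191	34	0	arterial	Common EC enhancer	0
Nrp1+91	Nrp1	109	0	0	inactive	Common EC enhancer	0
Nrp1+129	Nrp1	110	0	0	inactive	Common EC enhancer	0
Dll4-12	Dll4			0	arterial	Common EC enhancer	1
Dll4in3	Dll4			0	arterial	Common EC enhancer	1
Ece1in1	Ece1			0	arterial	Common EC enhancer	1
Flk1in10	Flk1			0	arterial	Uncalled	1
Hey1-18	Hey1			0	arterial	Common EC enhancer	1
Notch1+16	Notch1			0	arterial	Common EC enhancer	1
Sema6d-55	Sema6d			0	arterial	Common EC enhancer	1
Sox7+14	Sox7			0	arterial	Common EC enhancer	1
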