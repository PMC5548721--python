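# hand-constructed 20-gene expression fixture
gene_id	acc1	acc2	acc3	acc4	acc5	acc6	acc7
g01	1.0	1.0	1.0	1.0	1.0	0.0	0.0
g04	2.0	2.0	2.0	2.0	2.0	2.0	0.0
g05	1.5	1.5	1.5	1.5	1.5	0.0	0.0
g07	3.0	3.0	3.0	3.0	3.0	3.0	3.0
g08	0.8	0.8	0.8	0.8	0.8	0.0	0.0
g09	0.79	0.79	0.79	0.79	0.79	0.79	0.79
g10	10.0	10.0	10.0	10.0	0.0	0.0	0.0
g11	0.8	0.8	0.8	0.8	0.79	0.79	0.79
g12	50.0	50.0	50.0	50.0	50.0	50.0	50.0
g13	1.2	1.2	1.2	1.2	1.2	0.0	0.0
g14	5.0	5.0	5.0	5.0	5.0	5.0	0.0
g16	0.0	0.0	0.0	0.0	0.0	0.0	0.0
g17	0.8	0.8	0.8	0.8	0.8	0.0	0.0
g19	0.9	0.9	0.9	0.9	0.9	0.0	0.0
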