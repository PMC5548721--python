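# hand-constructed 20-gene expression fixture
gene_id	acc1	acc2	acc3	acc4	acc5	acc6	acc7
g03	1.0	1.0	1.0	1.0	1.0	0.0	0.0
g05	1.5	1.5	1.5	1.5	1.5	0.0	0.0
g06	1.1	1.1	1.1	1.1	1.1	0.0	0.0
g07	3.0	3.0	3.0	3.0	3.0	3.0	3.0
g09	0.79	0.79	0.79	0.79	0.79	0.79	0.79
g12	60.0	60.0	60.0	60.0	60.0	60.0	60.0
g15	100.0	100.0	100.0	100.0	100.0	100.0	100.0
g16	0.0	0.0	0.0	0.0	0.0	0.0	0.0
g17	0.8	0.8	0.8	0.8	0.8	0.0	0.0
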