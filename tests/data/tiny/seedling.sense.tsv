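# hand-constructed 20-gene expression fixture
gene_id	acc1	acc2	acc3	acc4	acc5	acc6	acc7
g02	1.0	1.0	1.0	1.0	1.0	0.0	0.0
g04	2.0	2.0	2.0	2.0	2.0	2.0	0.0
g06	1.1	1.1	1.1	1.1	1.1	0.0	0.0
g07	3.0	3.0	3.0	3.0	3.0	3.0	3.0
g09	0.79	0.79	0.79	0.79	0.79	0.79	0.79
g12	40.0	40.0	40.0	40.0	40.0	40.0	40.0
g13	1.2	1.2	1.2	1.2	1.2	0.0	0.0
g16	0.0	0.0	0.0	0.0	0.0	0.0	0.0
g18	2.0	2.0	2.0	2.0	2.0	2.0	0.0
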