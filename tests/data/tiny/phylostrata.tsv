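gene_id	phylostratum
g01	1
g02	1
g03	2
g04	2
g05	3
g06	3
g07	1
g08	4
g09	5
g10	6
g11	7
g12	1
g13	2
g14	8
g15	6
g16	12
g17	9
g18	4
g19	5
g20	12
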