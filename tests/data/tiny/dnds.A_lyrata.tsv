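gene_id	dN	dS
g01	0.1	1.0
g02	0.05	0.5
g03	0.2	1.0
g04	0.3	2.0
g05	0.15	0.3
g07	0.02	0.8
g09	0.6	1.0
g10	0.4	6.0
g12	0.01	1.0
g15	0.45	0.25
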