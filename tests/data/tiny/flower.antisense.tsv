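gene_id	acc1	acc2	acc3	acc4	acc5	acc6	acc7
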