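condition_id	replicate_id	gene_id	abundance_mmol_per_gDW
c1		g1	0.001
c1		g2	0.001
c1		g3	0.001
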