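condition_id	replicate_id	mu_per_h	carbon_exchange_id	uptake_mmol_per_gDW_h
c1		5	EX_A	10
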