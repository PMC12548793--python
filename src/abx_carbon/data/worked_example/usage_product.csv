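product_id,n_doses
CFZ-1G-FP,30
CFZ-3G-LC,20
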