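product_id,agent,dose_label,formulation,doses_per_day
CFZ-1G-FP,cefazolin,1 g/50 mL,frozen_premix,3
CFZ-3G-LC,cefazolin,3 g/100 mL,local_compound,3
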