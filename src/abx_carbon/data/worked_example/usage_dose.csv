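agent,dose_label,n_doses
cefazolin,1 g/50 mL,30
cefazolin,3 g/100 mL,20
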