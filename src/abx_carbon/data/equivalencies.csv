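name,unit_label,mtco2e_per_unit
miles driven by average gasoline-powered passenger vehicle,miles,0.000394
gallons of gasoline consumed,gallons,0.008887
number of smartphones charged,charges,0.00000822
tree seedlings grown for 10 years,seedlings,0.060
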