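# factor_table: EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
# mode: dot
# scenario: landfilled
agent,quantity,co2e_short_tons,co2e_metric_tons,waste_mass_short_tons,waste_mass_g,miles driven by average gasoline-powered passenger vehicle,gallons of gasoline consumed,number of smartphones charged,tree seedlings grown for 10 years,quantity (2dp),co2e_short_tons (2dp),co2e_metric_tons (2dp),waste_mass_short_tons (2dp),waste_mass_g (2dp),miles driven by average gasoline-powered passenger vehicle (2dp),gallons of gasoline consumed (2dp),number of smartphones charged (2dp),tree seedlings grown for 10 years (2dp)
cefazolin,100.0,0.0025917130281908458,0.0023511625096339253,0.03304701752368542,29979.75,5.967417537141943,0.2645620017591904,286.02950238855544,0.03918604182723209,100.00,0.00,0.00,0.03,29979.75,5.97,0.26,286.03,0.04
TOTAL,100.0,0.0025917130281908458,0.0023511625096339253,0.03304701752368542,29979.75,5.967417537141943,0.2645620017591904,286.02950238855544,0.03918604182723209,100.00,0.00,0.00,0.03,29979.75,5.97,0.26,286.03,0.04
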