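material,disposal_method,mtco2e_per_short_ton,source
aluminum cans,recycled,0.06,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
aluminum cans,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
aluminum cans,combusted,0.03,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
steel cans,recycled,0.30,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
steel cans,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
steel cans,combusted,0.03,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed metals,recycled,0.20,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed metals,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed metals,combusted,0.03,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
glass,recycled,0.05,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
glass,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
glass,combusted,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
hdpe,recycled,0.21,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
hdpe,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
hdpe,combusted,2.85,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
ldpe,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
ldpe,combusted,2.85,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
pet,recycled,0.21,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
pet,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
pet,combusted,2.07,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
polypropylene,recycled,0.21,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
polypropylene,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
polypropylene,combusted,2.89,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
polystyrene,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
polystyrene,combusted,3.07,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
pvc,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
pvc,combusted,1.28,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed plastics,recycled,0.21,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed plastics,landfilled,0.02,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed plastics,combusted,2.34,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
corrugated containers,recycled,0.09,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
corrugated containers,landfilled,1.17,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
corrugated containers,combusted,0.05,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed paper (general),recycled,0.09,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed paper (general),landfilled,1.22,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed paper (general),combusted,0.05,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
office paper,recycled,0.09,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
office paper,landfilled,1.79,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
office paper,combusted,0.05,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed recyclables,recycled,0.09,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed recyclables,landfilled,1.05,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed recyclables,combusted,0.11,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed msw,landfilled,0.58,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed msw,combusted,0.43,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed,landfilled,0.58,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
mixed,combusted,0.43,EPA GHG Emission Factors Hub waste table (WARM); transcribed 2025 edition
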