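product_id,item_id,site,count_per_dose
CFZ-1G-FP,PREMIX-BAG,siteA,1.0
CFZ-1G-FP,PREMIX-WRAP,siteA,1.0
CFZ-1G-FP,BOX-PREMIX,siteA,0.08333333333333333
CFZ-1G-FP,PREMIX-BAG,siteB,1.0
CFZ-1G-FP,PREMIX-WRAP,siteB,1.0
CFZ-1G-FP,BOX-PREMIX,siteB,0.08333333333333333
CFZ-3G-LC,VIAL-CFZ-10G,siteA,0.3333333333333333
CFZ-3G-LC,BOX-VIAL,siteA,0.3333333333333333
CFZ-3G-LC,DILUENT-BAG-100,siteA,1.0
CFZ-3G-LC,SYR-60,siteA,1.0
CFZ-3G-LC,VIAL-CFZ-10G,siteB,0.3333333333333333
CFZ-3G-LC,BOX-VIAL,siteB,0.3333333333333333
CFZ-3G-LC,DILUENT-BAG-100,siteB,1.0
CFZ-3G-LC,SYR-60,siteB,2.0
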