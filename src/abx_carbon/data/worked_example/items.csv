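item_id,name,role,material,site,mass_g
PREMIX-BAG,cefazolin 1 g/50 mL premix bag,drug_container,mixed plastics,siteA,45.12
PREMIX-BAG,cefazolin 1 g/50 mL premix bag,drug_container,mixed plastics,siteB,44.50
PREMIX-WRAP,premix overwrap,drug_packaging,ldpe,siteA,8.21
PREMIX-WRAP,premix overwrap,drug_packaging,ldpe,siteB,8.05
BOX-PREMIX,premix corrugated box,drug_packaging,corrugated containers,siteA,62.40
BOX-PREMIX,premix corrugated box,drug_packaging,corrugated containers,siteB,58.90
VIAL-CFZ-10G,cefazolin 10 g vial,drug_container,glass,siteA,32.10
VIAL-CFZ-10G,cefazolin 10 g vial,drug_container,glass,siteB,33.85
BOX-VIAL,vial paperboard box,drug_packaging,mixed paper (general),siteA,11.25
BOX-VIAL,vial paperboard box,drug_packaging,mixed paper (general),siteB,10.80
DILUENT-BAG-100,diluent bag 100 mL,preparation,mixed plastics,siteA,38.75
DILUENT-BAG-100,diluent bag 100 mL,preparation,mixed plastics,siteB,37.90
SYR-60,60 mL syringe,preparation,polypropylene,siteA,24.60
SYR-60,60 mL syringe,preparation,polypropylene,siteB,25.15
TUBING-PRIMARY,primary IV tubing set,administration,pvc,siteA,41.30
TUBING-PRIMARY,primary IV tubing set,administration,pvc,siteB,39.75
FLUSH-SYR,saline flush syringe,administration,polypropylene,siteA,12.45
FLUSH-SYR,saline flush syringe,administration,polypropylene,siteB,12.10
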