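raw,canonical
vancomycin hcl,vancomycin
vancomycin hydrochloride,vancomycin
cefazolin sodium,cefazolin
ceftriaxone sodium,ceftriaxone
cefepime hcl,cefepime
ampicillin sodium,ampicillin
ampicillin-sulbactam sodium,ampicillin-sulbactam
piperacillin-tazobactam sodium,piperacillin-tazobactam
pip-tazo,piperacillin-tazobactam
zosyn,piperacillin-tazobactam
unasyn,ampicillin-sulbactam
trimethoprim-sulfamethoxazole sodium,trimethoprim-sulfamethoxazole
tmp-smx,trimethoprim-sulfamethoxazole
bactrim,trimethoprim-sulfamethoxazole
sulfamethoxazole-trimethoprim,trimethoprim-sulfamethoxazole
metronidazole hcl,metronidazole
levofloxacin hemihydrate,levofloxacin
ciprofloxacin lactate,ciprofloxacin
azithromycin dihydrate,azithromycin
gentamicin sulfate,gentamicin
tobramycin sulfate,tobramycin
amikacin sulfate,amikacin
daptomycin sodium,daptomycin
linezolid iv,linezolid
meropenem trihydrate,meropenem
ertapenem sodium,ertapenem
imipenem-cilastatin sodium,imipenem-cilastatin
aztreonam lysine,aztreonam
acyclovir sodium,acyclovir
clindamycin phosphate,clindamycin
doxycycline hyclate,doxycycline
fluconazole iv,fluconazole
micafungin sodium,micafungin
caspofungin acetate,caspofungin
amphotericin b liposomal,amphotericin b
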