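site,item_id,count_per_day
siteA,TUBING-PRIMARY,1.0
siteA,FLUSH-SYR,4.0
siteB,TUBING-PRIMARY,1.0
siteB,FLUSH-SYR,2.0
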