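taxon,specimen_id,family,group,age_ma,endocranial_volume_cm3,ocw_mm
Dorudon atrox,UM 101222,Basilosauridae,cetacean,39,1173,126
Saghacetus osiris,BMNH 10228,Basilosauridae,cetacean,39,480,91.8
Zygorhiza kochii,USNM 16639,Basilosauridae,cetacean,37,917,112
Zygorhiza kochii,FMNH PM-459,Basilosauridae,cetacean,34,1189,120
Rodhocetus kasrani,GSP-UM 3012,Protocetidae,cetacean,47,290,88.7
Dalanistes ahmedi,GSP-UM 3106,Remingtonocetidae,cetacean,45,400,104.8
Remingtonocetus harudiensis,IITR-SB 2770,Remingtonocetidae,cetacean,42,253,87
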