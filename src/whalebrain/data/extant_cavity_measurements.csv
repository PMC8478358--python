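specimen_id,taxon,group,maturity,brain_mass_g,endocranial_volume_cm3,adnexa_mass_g
Goat (A),Capra hircus,terrestrial,adult,113.3,145,
Goat (C),Capra hircus,terrestrial,adult,121.5,149,
Goat (D),Capra hircus,terrestrial,adult,102.1,130,
Goat (E),Capra hircus,terrestrial,adult,99.3,132,
Pig (PGL 417),Sus scrofa,terrestrial,adult,128.5,186,
Pig (PGL 419),Sus scrofa,terrestrial,adult,140,176,13.4
Beluga (NSB-DWM 2019LDL10),Delphinapterus leucas,cetacean,adult,2074,2528,165
Bowhead (NSB-DWM 2008B11),Balaena mysticetus,cetacean,subadult,2948,8400,1238
Bowhead (NSB-DWM 2009B9),Balaena mysticetus,cetacean,subadult,2980,8900,
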