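product,category,group,energy_kcal_per_kg
maize,crop,maize,3560
banana,crop,banana,1140
sorghum,crop,sorghum,3430
cassava,crop,cassava,1530
beans,crop,beans,3410
coffee,crop,coffee,1250
groundnut,crop,other,5670
sweet_potato,crop,other,1050
millet,crop,other,3780
rice,crop,other,3600
cattle,livestock,cattle,2240
milk,livestock,cattle,640
poultry,livestock,poultry,1390
eggs,livestock,poultry,1430
goat,livestock,other,1090
pig,livestock,other,2630
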