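forest_id,forest_type,location,latitude,longitude,mat_c,ap_mm,species_richness,n_species_sampled
F01,Boreal forest,"Joensuu, North Karelia (Finland)",62.616,29.89,2.1,628,1,3
F02,Boreal forest,"Joensuu, North Karelia (Finland)",62.504,29.76,2.1,628,2,2
F03,Boreal forest,"Joensuu, North Karelia (Finland)",62.558,30.16,2.1,628,3,2
F04,Mountainous beech forest,"Carpathian mountains (Romania)",47.295,26.05,5.6,689,1,4
F05,Mountainous beech forest,"Carpathian mountains (Romania)",47.294,26.05,5.6,689,2,4
F06,Mountainous beech forest,"Carpathian mountains (Romania)",47.292,26.05,5.6,689,3,3
F07,Mountainous beech forest,"Carpathian mountains (Romania)",47.291,26.05,5.6,689,4,2
F08,Mediterranean mixed forest,"Alto Tajo Natural Park (Spain)",40.731,-2.25,9.9,533,1,4
F09,Mediterranean mixed forest,"Alto Tajo Natural Park (Spain)",40.713,-2.19,9.9,533,2,4
F10,Mediterranean mixed forest,"Alto Tajo Natural Park (Spain)",40.698,-2.13,9.9,533,3,2
F11,Tropical lowland dry deciduous forest,"Inpa, Concepcion, Santa Cruz (Bolivia)",-16.117,-61.72,23.5,1124,34,52
F12,"Riparian, chaparral, broadleaf evergreen forest","Jasper Ridge Biological Preserve (California, USA)",37.4,-122.25,13.8,598,54,43
F13,Tropical lowland semi-deciduous seasonal moist forest,Soberania National Park (Panama),9.162,-79.75,26,2553,131,16
F14,Lowland tropical rainforest,Acarouany (French Guiana),5.544,-53.81,26.5,2237,148,11
F15,Lowland tropical rainforest,Paracou (French Guiana),5.272,-52.93,25.8,2821,150,35
F16,Lowland tropical rainforest,BAFOG (French Guiana),5.494,-53.99,26.4,2460,156,11
F17,Lowland tropical rainforest,Nouragues (French Guiana),4.087,-52.67,24.8,3337,197,24
F18,Lowland tropical rainforest,Montagne Tortue (French Guiana),4.219,-52.41,24.6,3591,213,14
F19,Lowland tropical rainforest,Saut Lavilette (French Guiana),4.151,-52.2,25.7,3590,224,10
F20,Evergreen lowland tropical rainforest,Yasuni National Park (Ecuador),0.683,-76.4,25,3129,251,59
F21,Lowland tropical rainforest,"BDFFP Reserve, Central Amazon (Brazil)",-2.433,-59.83,27,2410,284,16
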