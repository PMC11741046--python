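id,label,sector,source,sink,category,material,amount_c_t,variation_pct,fossil
a_feed_in,Purchased feeds,animal,external,animal,input,plant_material,5.2,10,false
n_feeds,Self-produced feeds and litter,plant,plant,animal,internal,plant_material,167.2,10,false
a_gases,Animal gases,animal,animal,air,output,custom,106.9,10,false
n_manure,Manure,animal,animal,soil,internal,plant_material,44.7,10,false
a_manure_gas,Manure,animal,animal,air,output,custom,12.2,10,false
a_energy,Energy,animal,animal,air,output,electricity,0.2,10,true
a_sold,Animals sold,animal,animal,external,output,live_weight,7.3,10,false
p_npe,Net plant exchange,plant,air,plant,input,co2,357.4,10,false
p_fuel_in,Fuel,plant,external,plant,input,oil,15.6,10,true
n_residues,Crop residues,plant,plant,soil,internal,plant_material,80.9,10,false
p_fuel_gas,Gas emissions from fuel combustion,plant,plant,air,output,co2,15.6,10,true
p_sold,Plant products sold,plant,plant,external,output,plant_material,27.1,10,false
s_fert,Fertilisers,soil,external,soil,input,urea,0.8,10,false
s_depletion,Depletion of organic C,soil,soil,air,output,co2,126.4,10,false
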