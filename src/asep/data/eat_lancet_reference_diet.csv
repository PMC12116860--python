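group_name,energy_kcal,is_animal_source
Whole milk or derivative equivalents,153,True
Beef and lamb,15,True
Pork,15,True
Chicken and other poultry,62,True
Eggs,19,True
Fish,40,True
Lard or tallow,36,True
All plant source food groups,2160,False
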