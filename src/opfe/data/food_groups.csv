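code,name
cereals,Cereals
roots_tubers,Roots and tubers
vegetables,Vegetables
mushrooms_algae,Mushrooms and edible algae
meat_poultry_offal,Meat poultry and offal
eggs,Eggs
fish_seafood,Fish and seafood
pulses_legumes,Pulses and legumes
nuts,Nuts
dairy,Dairy products
fruits,Fruits
miscellaneous,Miscellaneous condiments snacks and beverages
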