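level1,code1,level2,code2,short_name,description
Meal,1,Staple,1-1,ST,Rice is the major component with some meat and eggs
Meal,1,Noodles and dumplings,1-2,ND,Wheat and rice are the main components with some meat and vegetables
Meal,1,Set meal,1-3,SET,Rice with meat/egg and vegetables as main components
Meal,1,Seafood,1-4,SF,Seafood and other aquatic products as main components
Meal,1,Pot,1-5,POT,Vegetables and soy and aquatic products as main ingredients
Meal,1,Fried and BBQ,1-6,F_BBQ,Meat cooked fried or smoked as the main food
Meal,1,Western fast-food,1-7,WFF,Western fast food such as hamburgers and pizza
Meal,1,Healthy and light recipes,1-8,HLR,Light meals drawing on most food groups
Snacks and Beverage,2,Dessert,2-1,DT,Cakes doughnuts ice cream and similar
Snacks and Beverage,2,Snacks,2-2,SK,Packed snacks such as chicken wings nuts and popcorn
Snacks and Beverage,2,Alcoholic beverage,2-3,AB,Beer wine and other alcoholic drinks
Snacks and Beverage,2,Synthetic beverage,2-4,SB,Carbonated and other synthetic drinks
Snacks and Beverage,2,Stimulating drinks,2-5,SD,Functional drinks tea and coffee
Other,3,Unknown,3-1,UN,Food or outlet outside the above categories
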