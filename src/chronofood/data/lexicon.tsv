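entry	nova	flags	special
apple	1
banana	1
salad	1
rice	1
pasta	1
potato	1
chicken	1
egg	1
oatmeal	1
yogurt	1
milk	1
nuts	1
fish	1
soup	1
coffee	1	C
espresso	1	C
cafe	1	C
kaffee	1	C
black tea	1	C
green tea	1	C
herbal tea	1	D
orange juice	1	S
coffee milk	1	C
butter	2
olive oil	2
sugar	2
honey	2
coffee sugar milk	2	CS
cheese	3
bread	3
ham	3
jam	3
smoked salmon	3
beer	3	A
wine	3	A
pizza	4
ham pizza	4
croissant	4
chocolate	4
biscuit	4
toast	4
burger	4
ice cream	4
chips	4
cereal bar	4
soy drink	4	D
coca-cola	4	CS
cola	4	CS
soda	4	S
energy drink	4	CS
whisky	4	A
water			water
sparkling water			water
medication			medication
aspirin			medication
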