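# Measurement units for medication dosing.
# term	canonical	concept_id
ml	ml	U:ml
milliliter	ml	U:ml
milliliters	ml	U:ml
mg	mg	U:mg
milligram	mg	U:mg
milligrams	mg	U:mg
mcg	mcg	U:mcg
g	g	U:g
gram	g	U:g
grams	g	U:g
oz	oz	U:oz
ounce	oz	U:oz
ounces	oz	U:oz
tsp	tsp	U:tsp
teaspoon	tsp	U:tsp
teaspoons	tsp	U:tsp
tablespoon	tbsp	U:tbsp
tablet	tablet	U:tablet
tablets	tablet	U:tablet
capsule	capsule	U:capsule
capsules	capsule	U:capsule
drop	drop	U:drop
drops	drop	U:drop
puff	puff	U:puff
puffs	puff	U:puff
units	unit	U:unit
iu	iu	U:iu
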