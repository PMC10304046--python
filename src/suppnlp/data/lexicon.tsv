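keyword	category
acidophilus	probiotic
aloe	aloe vera
astragalus	astragalus
biotin	biotin
calcium	calcium
cholecalciferol	vitamin d3
chondroitin	chondroitin
cinnamon	cinnamon
coenzyme	coenzyme q10
cranberry	cranberry
crea	creatine
creat	creatine
creatine	creatine
creatinin	creatine
creatinine	creatine
creatining	creatine
creatnine	creatine
cvitamin	vitamin c
cyancobalamin	vitamin b12
cyanocobalamin	vitamin b12
cyanocobalamine	vitamin b12
cyanocobalmin	vitamin b12
dhea	dhea
digitalis	digitalis
echinacea	echinacea
ergocalciferol	vitamin d2
fe	iron
ferr	iron
fiber	fiber
fish	fish oil
fishoil	fish oil
flex	glucosamine
flexion	glucosamine
flx	glucosamine
folic	folic acid
garlic	garlic
ginger	ginger
ginkgo	ginkgo biloba
ginko	ginkgo biloba
ginseng	ginseng
glucosamine	glucosamine
irn	iron
iron	iron
krill	fish oil
licorice	licorice
magnesium	magnesium
melatonin	melatonin
mlfolic	folic acid
multivitamin	multivitamin
multivitamins	multivitamin
multivits	multivitamin
niacin	vitamin b3
oregano	oregano
palmetto	palmetto
potasium	potassium
potass	potassium
potassium	potassium
potassuim	potassium
pottasium	potassium
pyridoxine	vitamin b6
retinal	vitamin a
riboflavin	vitamin b2
tea	tea
thaimine	thiamine
thiamin	thiamine
thiamine	thiamine
thistle	thistle
tumeric	curcumin
turmeric	curcumin
vera	aloe vera
viamin	multivitamin
viatmin	multivitamin
vit	multivitamin
vita	multivitamin
vitamin	multivitamin
vitamine	multivitamin
vitd	vitamin d3
vitmain	multivitamin
vits	multivitamin
willow	willow
yeast	yeast
zinc	zinc
zn	zinc
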