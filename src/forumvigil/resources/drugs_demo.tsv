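surface_form	canonical	class
tramadol	tramadol	opioid
topalgic	tramadol	opioid
contramal	tramadol	opioid
codeine	codeine	opioid
morphine	morphine	opioid
skenan	morphine	opioid
oxycodone	oxycodone	opioid
oxycontin	oxycodone	opioid
ibuprofene	ibuprofen	nsaid
advil	ibuprofen	nsaid
nurofen	ibuprofen	nsaid
aspirine	aspirin	nsaid
aspegic	aspirin	nsaid
naproxene	naproxen	nsaid
ketoprofene	ketoprofen	nsaid
profenid	ketoprofen	nsaid
diclofenac	diclofenac	nsaid
voltarene	diclofenac	nsaid
cafeine	caffeine	other
amoxicilline	amoxicillin	other
clamoxyl	amoxicillin	other
omeprazole	omeprazole	other
mopral	omeprazole	other
levothyrox	levothyroxine	other
xanax	alprazolam	other
valium	diazepam	other
lexomil	bromazepam	other
prozac	fluoxetine	other
metformine	metformin	other
spasfon	phloroglucinol	other
smecta	diosmectite	other
gaviscon	alginate	other
imodium	loperamide	other
toplexil	oxomemazine	other
vitamine c	ascorbic acid	other
magnesium	magnesium	other
zopiclone	zopiclone	other
stilnox	zolpidem	other
laroxyl	amitriptyline	other
lyrica	pregabalin	other
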