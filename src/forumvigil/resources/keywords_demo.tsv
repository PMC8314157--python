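keyword	category	canonical_brand
doliprane	paracetamol_only	Doliprane
dafalgan	paracetamol_only	Dafalgan
efferalgan	paracetamol_only	Efferalgan
paracetamol	paracetamol_only	Paracetamol
panadol	paracetamol_only	Panadol
dolko	paracetamol_only	Dolko
geluprane	paracetamol_only	Geluprane
dolotec	paracetamol_only	Dolotec
ixprim	paracetamol_opioid	Ixprim
codoliprane	paracetamol_opioid	Codoliprane
dafalgan codeine	paracetamol_opioid	Dafalgan Codeine
klipal codeine	paracetamol_opioid	Klipal Codeine
lamaline	paracetamol_opioid	Lamaline
zaldiar	paracetamol_opioid	Zaldiar
lindilane	paracetamol_opioid	Lindilane
actifed	paracetamol_other	Actifed
dolirhume	paracetamol_other	Dolirhume
fervex	paracetamol_other	Fervex
humex rhume	paracetamol_other	Humex Rhume
lemsip	paracetamol_other	Lemsip
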