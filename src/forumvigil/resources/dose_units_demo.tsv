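product	mg_per_unit
Doliprane	1000
Dafalgan	1000
Efferalgan	1000
Paracetamol	1000
Panadol	500
Dolko	500
Geluprane	500
Dolotec	500
Ixprim	325
Codoliprane	500
Dafalgan Codeine	500
Klipal Codeine	600
Zaldiar	325
Lamaline	300
Lindilane	400
Actifed	500
Dolirhume	500
Fervex	500
Humex Rhume	500
Lemsip	650
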