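term	field
pris	intake
prends	intake
avale	intake
gobe	intake
pris ce matin	intake
conseille	nonintake
recommande	nonintake
prescrit	nonintake
parle	nonintake
entendu	nonintake
question	nonintake
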