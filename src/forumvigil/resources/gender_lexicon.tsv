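form	gender
allee	female
alle	male
contente	female
content	male
inquiete	female
inquiet	male
epuisee	female
epuise	male
heureuse	female
heureux	male
desolee	female
desole	male
enceinte	female
soulagee	female
soulage	male
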