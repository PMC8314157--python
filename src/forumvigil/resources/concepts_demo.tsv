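surface_form	concept_id	preferred_term	layer
douleur	C_PAIN	pain	standard
mal partout	C_PAIN	pain	consumer
fievre	C_PYREXIA	pyrexia	standard
temperature	C_PYREXIA	pyrexia	consumer
fatigue	C_FATIGUE	fatigue	standard
epuisement	C_FATIGUE	fatigue	consumer
nausee	C_NAUSEA	nausea	standard
envie de vomir	C_NAUSEA	nausea	consumer
vomissement	C_VOMITING	vomiting	standard
mal de tete	C_HEADACHE	headache	standard
mal au crane	C_HEADACHE	headache	consumer
migraine	C_MIGRAINE	migraine	standard
dependance	C_DEPENDENCE	dependence	standard
insomnie	C_INSOMNIA	insomnia	standard
vertige	C_DIZZINESS	dizziness	standard
grossesse	C_PREGNANCY	pregnancy	standard
rhume	C_NASOPHARYNGITIS	nasopharyngitis	standard
nez bouche	C_NASOPHARYNGITIS	nasopharyngitis	consumer
somnolence	C_SOMNOLENCE	somnolence	standard
anxiete	C_ANXIETY	anxiety	standard
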