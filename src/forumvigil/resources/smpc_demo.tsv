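category	concept_id
paracetamol_only	C_PAIN
paracetamol_only	C_PYREXIA
paracetamol_only	C_HEADACHE
paracetamol_only	C_MIGRAINE
paracetamol_opioid	C_PAIN
paracetamol_opioid	C_HEADACHE
paracetamol_opioid	C_MIGRAINE
paracetamol_other	C_PAIN
paracetamol_other	C_PYREXIA
paracetamol_other	C_NASOPHARYNGITIS
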