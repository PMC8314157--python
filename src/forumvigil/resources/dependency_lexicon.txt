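# Dependency lexical field: words and expressions linked to drug dependence,
# assembled the way an expert-reviewed sample of dependence messages would be.
accro
dependance
dependant
sevrage
manque
addiction
desintoxication
augmenter les doses
impossible d'arreter
besoin imperieux
rechute
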