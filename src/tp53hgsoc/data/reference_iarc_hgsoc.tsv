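category	count	n_cases
GOF	271	1249
LOF	261	1249
unclassified	717	1249
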