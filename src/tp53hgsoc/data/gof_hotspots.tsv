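protein_change
P151S
Y163C
R175H
L194R
Y220C
R248Q
R248W
R273C
R273H
R273L
R282W
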