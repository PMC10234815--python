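X	0	60000
X	2699520	154931043
X	155260560	155270560
Y	0	10000
Y	2649520	59034049
Y	59363566	59373566
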