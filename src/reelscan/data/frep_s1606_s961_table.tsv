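protein	sample1	sample2	control1	control2	element
DBN1	12	3	0	0	S1606
POLB	4	3	0	0	S1606
MVP	3	3	0	0	S1606
PABPC1	6	2	0	0	S1606
SERPINH1	3	2	0	0	S1606
FOXC2	2	1	0	0	S961
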