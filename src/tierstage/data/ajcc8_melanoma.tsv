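# AJCC 8th edition stage groups, cutaneous melanoma.
# Melanoma is the one shipped site where clinical (context c) and
# pathological (context p) stage grouping differ: clinically, node-positive
# M0 disease is Stage III undivided and T1b N0 is IB; pathologically,
# stage III subdivides into IIIA-IIID by T and N and pT1b pN0 is IA.
#leaves	t	is,1a,1b,2a,2b,3a,3b,4a,4b
#leaves	n	0,1a,1b,1c,2a,2b,2c,3a,3b,3c
#leaves	m	0,1a,1b,1c,1d
t	n	m	stage	context
is	0	0	0	c
1a	0	0	IA	c
1b,2a	0	0	IB	c
2b,3a	0	0	IIA	c
3b,4a	0	0	IIB	c
4b	0	0	IIC	c
*	1a,1b,1c,2a,2b,2c,3a,3b,3c	0	III	c
is	0	0	0	p
1a,1b	0	0	IA	p
2a	0	0	IB	p
2b,3a	0	0	IIA	p
3b,4a	0	0	IIB	p
4b	0	0	IIC	p
1a,1b,2a	1a,2a	0	IIIA	p
1a,1b,2a	1b,1c,2b	0	IIIB	p
2b,3a	1a,1b,1c,2a,2b	0	IIIB	p
1a,1b,2a	2c,3a,3b,3c	0	IIIC	p
2b,3a	2c,3a,3b,3c	0	IIIC	p
3b,4a	1a,1b,1c,2a,2b,2c,3a,3b,3c	0	IIIC	p
4b	1a,1b,1c,2a,2b,2c	0	IIIC	p
4b	3a,3b,3c	0	IIID	p
*	*	1a,1b,1c,1d	IV	*
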