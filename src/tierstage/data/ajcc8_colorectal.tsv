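# AJCC 8th edition anatomic stage groups, colon and rectum.
# Leaf categories are the most specific tokens per axis; rows list
# comma-separated leaf tokens, "*" = any leaf, context "*" = clinical and
# pathological staging share one table for this site.
#leaves	t	is,1,2,3,4a,4b
#leaves	n	0,1a,1b,1c,2a,2b
#leaves	m	0,1a,1b,1c
t	n	m	stage	context
is	0	0	0	*
1,2	0	0	I	*
3	0	0	IIA	*
4a	0	0	IIB	*
4b	0	0	IIC	*
1,2	1a,1b,1c	0	IIIA	*
1	2a	0	IIIA	*
2,3	2a	0	IIIB	*
3,4a	1a,1b,1c	0	IIIB	*
1,2	2b	0	IIIB	*
4a	2a	0	IIIC	*
3,4a	2b	0	IIIC	*
4b	1a,1b,1c,2a,2b	0	IIIC	*
*	*	1a	IVA	*
*	*	1b	IVB	*
*	*	1c	IVC	*
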