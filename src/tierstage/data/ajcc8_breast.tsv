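# AJCC 8th edition ANATOMIC stage groups, breast.
# The prognostic table (receptor status, grade) is deliberately not shipped:
# this engine captures anatomic stage only.
# N1mi (micrometastases) is a distinct leaf: it maps to IB only with T0/T1;
# with larger tumours it groups with N1 (AJCC anatomic convention).
#leaves	t	is,0,1,2,3,4
#leaves	n	0,1mi,1,2,3
#leaves	m	0,1
t	n	m	stage	context
is	0	0	0	*
1	0	0	IA	*
0,1	1mi	0	IB	*
0,1	1	0	IIA	*
2	0	0	IIA	*
2	1mi,1	0	IIB	*
3	0	0	IIB	*
0,1,2	2	0	IIIA	*
3	1mi,1,2	0	IIIA	*
4	0,1mi,1,2	0	IIIB	*
*	3	0	IIIC	*
*	*	1	IV	*
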