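# Sub-stage -> umbrella (main stage category) map, AJCC 8e labels.
stage	umbrella
0	0
I	I
IA	I
IB	I
II	II
IIA	II
IIB	II
IIC	II
III	III
IIIA	III
IIIB	III
IIIC	III
IIID	III
IV	IV
IVA	IV
IVB	IV
IVC	IV
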