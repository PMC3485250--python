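scenario	param:N	stat:s1	stat:s2
A	100	1	2
B	200	2	0
C	300	4	6
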