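# Canonical probe-pair alphabet.  The four published mappings are
# (4,3)->C, (3,12)->I, (12,10)->J and the repeat pair (1,1)->Z; the
# remaining assignments complete a consistent probe walk for the shipped
# cassette world and are replaceable by editing this file.
probe_from	probe_to	symbol	repeat
2	5	M	0
5	4	H	0
4	3	C	0
3	12	I	0
12	10	J	0
10	6	K	0
6	2	L	0
2	1	F	0
1	5	G	0
2	3	A	0
12	6	R	0
1	1	Z	1
2	4	S	0
3	7	T	0
7	8	U	0
8	9	V	0
9	11	W	0
11	13	X	0
13	10	Y	0
3	14	N	0
14	12	O	0
1	4	P	0
10	15	Q	0
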