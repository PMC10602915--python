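aa	trna_name	base34	base35	base36	wobble_set
F	Phe	Gm	A	A	U,C
L	Leu1	C	A	G	G
L	Leu2	G	A	G	U,C
L	Leu3	cmo5U	A	G	U,C,A,G
L	Leu4	cmnm5Um	A	A	A,G
L	Leu5	C	A	A	G
I	Ile1	G	A	U	U,C
I	Ile2	k2C	A	U	A
M	Met	ac4C	A	U	G
V	Val1	cmo5U	A	C	U,C,A,G
V	Val2	G	A	C	U,C
S	Ser1	mcmo5U	G	A	U,C,A,G
S	Ser2	C	G	A	G
S	Ser3	G	G	A	U,C
S	Ser5	G	C	U	U,C
P	Pro1	C	G	G	G
P	Pro2	G	G	G	U,C
P	Pro3	cmo5U	G	G	U,C,A,G
T	Thr1	G	G	U	U,C
T	Thr2	C	G	U	G
T	Thr4	cmo5U	G	U	U,C,A,G
A	Ala1	cmo5U	G	C	U,C,A,G
A	Ala2	G	G	C	U,C
Y	Tyr	Q	U	A	U,C
H	His	Q	U	G	U,C
Q	Gln1	mnm5s2U	U	G	A,G
Q	Gln2	C	U	G	G
N	Asn	Q	U	U	U,C
K	Lys	mnm5s2U	U	U	A,G
D	Asp	Q	U	C	U,C
E	Glu	mnm5s2U	U	C	A,G
C	Cys	G	C	A	U,C
W	Trp	C	C	A	G
R	Arg2	I	C	G	U,C,A
R	Arg1	C	C	G	G
R	Arg4	C	C	U	G
R	Arg5	mnm5U	C	U	A,G
G	Gly1	C	C	C	G
G	Gly2	G	C	C	U,C
G	Gly3	mnm5U	C	C	A,G
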