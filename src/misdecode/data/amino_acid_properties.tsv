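aa	group	hydropathy	volume_A3	pI
F	U	2.8	189.9	5.48
L	U	3.8	166.7	5.98
I	U	4.5	166.7	6.02
M	U	1.9	162.9	5.74
V	U	4.2	140.0	5.96
S	C	-0.8	89.0	5.68
P	C	-1.6	112.7	6.30
T	C	-0.7	116.1	5.60
A	C	1.8	88.6	6.00
Y	A	-1.3	193.6	5.66
H	A	-3.2	153.2	7.59
Q	A	-3.5	143.8	5.65
N	A	-3.5	114.1	5.41
K	A	-3.9	168.6	9.74
D	A	-3.5	111.1	2.77
E	A	-3.5	138.4	3.22
C	G	2.5	108.5	5.07
W	G	-0.9	227.8	5.89
R	G	-4.5	173.4	10.76
G	G	-0.4	60.1	5.97
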