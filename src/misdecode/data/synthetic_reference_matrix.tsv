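# SYNTHETIC benchmark matrix: constructed by constrained integer programming to reproduce the published aggregate statistics; not measured data. See misdecode.reference.
codon	F	L	I	M	V	S	P	T	A	Y	H	Q	N	K	D	E	C	W	R	G
UUU	NA	2	0	0	4	4	3	4	0	3	0	1	0	0	0	0	0	0	1	0
UUC	NA	4	2	5	0	3	3	4	4	0	0	0	0	0	0	0	1	0	5	0
UUA	2	NA	4	3	5	0	2	2	4	0	0	5	0	2	0	0	3	0	4	5
UUG	5	NA	0	1	2	0	0	3	5	1	0	0	0	0	0	2	0	2	0	0
UCU	1	0	3	3	3	NA	5	3	3	4	0	0	0	0	0	0	0	0	0	1
UCC	1	0	2	5	0	NA	1	2	5	0	4	0	0	0	0	2	0	5	0	5
UCA	2	0	0	0	0	NA	1	5	5	0	0	4	0	4	0	0	0	3	3	0
UCG	0	3	0	0	0	NA	3	3	1	0	0	0	0	0	0	0	3	0	0	4
UAU	0	0	0	0	0	0	0	0	0	NA	4	0	0	0	2	0	0	0	0	0
UAC	3	5	3	0	0	0	2	0	0	NA	3	0	0	0	4	0	0	0	0	0
UGU	0	0	0	0	0	5	0	0	0	3	0	0	0	3	0	0	NA	0	0	0
UGC	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	NA	4	0	0
UGG	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	NA	5	4
CUU	4	NA	3	0	2	4	4	1	0	0	0	0	0	4	0	0	0	0	0	0
CUC	2	NA	3	5	4	2	2	0	4	3	0	0	0	0	0	0	0	5	0	5
CUA	5	NA	3	3	4	0	1	3	4	0	0	0	0	0	0	2	0	0	0	0
CUG	5	NA	2	3	3	0	1	3	5	0	3	1	5	0	0	0	0	4	3	0
CCU	2	1	0	4	5	3	NA	3	0	1	0	0	0	4	1	0	0	0	0	0
CCC	3	0	0	4	0	5	NA	0	5	2	0	0	0	0	0	0	0	0	4	0
CCA	1	0	2	0	1	4	NA	1	2	0	1	4	0	0	0	0	0	5	0	0
CCG	0	0	0	3	1	1	NA	5	4	0	0	4	0	0	0	0	0	1	0	4
CAU	0	3	0	0	0	0	2	0	0	0	NA	0	1	0	0	0	1	0	0	0
CAC	0	0	0	0	0	4	1	0	0	0	NA	1	2	0	0	0	0	0	0	2
CAA	0	0	0	0	0	0	0	0	0	0	0	NA	0	0	0	0	0	3	5	0
CAG	0	0	0	0	0	0	1	0	0	0	0	NA	0	0	0	0	0	0	1	0
CGU	0	0	5	0	0	0	0	0	0	0	5	0	0	0	0	0	0	0	NA	0
CGC	0	0	0	0	0	4	4	0	0	0	1	0	0	0	0	0	0	0	NA	0
CGA	0	0	0	0	0	0	0	0	0	0	0	3	0	0	0	0	0	0	NA	0
CGG	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	NA	0
AUU	2	5	NA	5	3	3	4	5	2	5	0	5	0	0	0	0	4	0	0	0
AUC	1	3	NA	5	2	3	1	4	3	0	0	0	3	0	0	0	0	0	0	0
AUA	0	4	NA	2	2	0	1	4	4	0	0	0	0	0	2	0	1	0	0	0
AUG	5	4	1	NA	1	0	5	4	0	0	0	0	1	0	0	0	0	1	2	0
ACU	2	2	0	0	2	1	3	NA	1	3	2	0	0	0	0	0	0	0	0	0
ACC	1	0	1	0	0	5	2	NA	0	0	0	0	5	0	0	0	0	0	0	4
ACA	0	1	3	0	4	3	4	NA	5	0	0	0	0	0	0	2	0	0	0	0
ACG	4	2	0	3	4	1	0	NA	5	0	0	0	0	0	1	0	0	0	0	0
AAU	0	0	0	0	0	0	0	0	4	4	5	0	NA	1	0	0	0	0	0	0
AAC	0	0	0	0	0	4	0	0	1	0	0	0	NA	2	2	0	0	0	0	1
AAA	0	0	0	0	0	0	0	0	4	0	0	0	0	NA	3	0	0	0	0	0
AAG	0	1	0	1	3	0	0	4	0	0	0	0	4	NA	0	0	0	0	3	0
AGU	0	0	0	0	0	NA	0	0	0	0	0	0	3	0	0	0	0	0	0	0
AGC	0	0	0	0	0	NA	0	0	0	0	0	2	5	0	0	0	3	0	5	0
AGA	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	NA	1
AGG	0	0	0	0	0	0	0	5	0	0	0	0	0	5	0	0	0	0	NA	0
GUU	4	2	3	4	NA	4	0	0	4	0	0	0	0	0	0	0	2	0	0	5
GUC	5	4	5	4	NA	4	2	4	4	0	4	0	4	0	0	0	2	0	0	3
GUA	0	1	1	1	NA	5	4	0	3	3	0	0	0	0	5	4	0	5	4	5
GUG	0	4	2	1	NA	3	0	0	4	0	0	0	0	0	4	1	0	0	0	0
GCU	0	5	0	0	5	4	3	5	NA	0	0	0	0	0	0	5	0	0	0	0
GCC	4	2	5	0	3	5	2	5	NA	0	0	0	0	0	1	0	0	0	0	3
GCA	5	1	0	2	2	3	3	2	NA	0	0	0	0	0	0	0	0	0	0	2
GCG	0	0	0	0	5	4	4	3	NA	0	0	0	0	0	1	0	0	0	0	5
GAU	0	0	0	0	0	0	0	0	2	0	2	0	5	0	NA	0	0	0	2	0
GAC	3	2	0	0	0	0	0	0	0	0	2	0	0	0	NA	5	0	0	0	2
GAA	0	0	1	0	0	0	0	0	3	0	1	0	0	0	0	NA	4	0	0	0
GAG	0	2	2	0	4	1	0	0	1	0	0	0	0	0	0	NA	4	0	3	3
GGU	0	0	0	0	0	1	0	0	3	0	0	4	0	0	4	0	0	0	0	NA
GGC	0	0	0	3	0	5	0	0	0	0	0	0	0	0	0	0	0	0	0	NA
GGA	0	0	0	0	0	0	0	0	5	0	0	0	0	0	0	2	0	0	5	NA
GGG	0	0	0	0	0	0	0	0	0	2	0	0	2	0	0	0	0	4	0	NA
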