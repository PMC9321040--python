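codon	aa	count
UUU	F	317
UUC	F	51
UUA	L	372
UUG	L	35
CUU	L	65
CUC	L	7
CUA	L	86
CUG	L	3
AUU	I	346
AUC	I	44
AUA	M	257
AUG	M	19
GUU	V	73
GUC	V	5
GUA	V	84
GUG	V	4
UCU	S	112
UCC	S	12
UCA	S	83
UCG	S	4
CCU	P	64
CCC	P	16
CCA	P	44
CCG	P	3
ACU	T	73
ACC	T	22
ACA	T	75
ACG	T	4
GCU	A	79
GCC	A	29
GCA	A	47
GCG	A	2
UAU	Y	141
UAC	Y	40
CAU	H	54
CAC	H	15
CAA	Q	57
CAG	Q	7
AAU	N	169
AAC	N	22
AAA	K	101
AAG	K	15
GAU	D	59
GAC	D	7
GAA	E	65
GAG	E	12
UGU	C	31
UGC	C	6
UGA	W	85
UGG	W	9
CGU	R	15
CGC	R	3
CGA	R	27
CGG	R	8
AGU	S	30
AGC	S	5
AGA	S	81
AGG	S	15
GGU	G	40
GGC	G	19
GGA	G	93
GGG	G	33
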