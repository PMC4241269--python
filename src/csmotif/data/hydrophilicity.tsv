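residue	hydrophilicity
A	-0.31
C	-1.54
D	0.77
E	0.64
F	-1.79
G	0.00
H	-0.13
I	-1.80
K	0.99
L	-1.70
M	-1.23
N	0.60
P	-0.72
Q	0.22
R	1.01
S	0.04
T	-0.26
V	-1.22
W	-2.25
Y	-0.96
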