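# Amino-acid background frequencies (UniProtKB/Swiss-Prot composition, %).
# Renormalized to sum to 1 at load time. Override with any 20-line
# <one-letter>\t<frequency> table via the background= arguments.
A	8.25
C	1.38
D	5.45
E	6.72
F	3.86
G	7.07
H	2.27
I	5.91
K	5.80
L	9.65
M	2.41
N	4.06
P	4.74
Q	3.93
R	5.53
S	6.65
T	5.36
V	6.86
W	1.10
Y	2.92
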