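residue	frequency
A	0.0825
R	0.0553
N	0.0406
D	0.0545
C	0.0138
Q	0.0393
E	0.0672
G	0.0707
H	0.0227
I	0.0591
L	0.0965
K	0.0580
M	0.0241
F	0.0386
P	0.0474
S	0.0665
T	0.0536
W	0.0110
Y	0.0292
V	0.0686
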