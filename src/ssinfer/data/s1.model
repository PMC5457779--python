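n_dep	5
alpha	5	10	10	8	10
beta	10	10	10	10	10
G1	0	0	1	0	-1
G2	2	0	0	0	0
G3	0	-1	0	0	0
G4	0	0	2	0	-1
G5	0	0	0	2	0
H1	2	0	0	0	0
H2	0	2	0	0	0
H3	0	-1	2	0	0
H4	0	0	0	2	0
H5	0	0	0	0	2
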