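n_dep	5
alpha	1.0005999999999999	1.6496999999999999	0.4536	0.23649999999999999	1.4059999999999999
beta	1.6496999999999999	0.57930000000000004	0.24560000000000001	2.0891999999999999	2.9437000000000002
G1	0	-0.049200000000000001	0	0	0	1	0	0	0	0	0	0	0
G2	0.55820000000000003	0	0	0	0.0465	0	1	0	0	0	0	0	0
G3	0	0.44069999999999998	0	0	-0.26650000000000001	0	0	1	0	0	0	0	0
G4	0	0	0.52849999999999997	0	0.099400000000000002	0	0	0	1	0	0	0	0
G5	0	0	0.26050000000000001	0.152	0.073899999999999993	0	0	0	0.5	0.5	0	0	0
H1	0.55820000000000003	0	0	0	0.045600000000000002	0	1	0	0	0	0	0	0
H2	0	0.50970000000000004	0	0	-0.2218	0	0	0.83220000000000005	0	0	0.1678	0	0
H3	0	0	0.4506	0.0441	0.091999999999999998	0	0	0	0.85470000000000002	0	0	0.14530000000000001	0
H4	0	0	-0.0074999999999999997	0.30399999999999999	0.048399999999999999	0	0	0	0	1	0	0	0
H5	0.19620000000000001	0.17910000000000001	0	0	0.2354	0	0.35139999999999999	0.29249999999999998	0	0	0.058900000000000001	0	0.29699999999999999
fixed_vars	47.5	24.100000000000001	53.899999999999999	91.400000000000006	18.100000000000001	82.900000000000006	92.400000000000006	1
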