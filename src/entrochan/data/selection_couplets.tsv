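Channel	2	5	8	11	14	17	20	23	26	29	Total
Fp1	1	1	1	1	1	1	1	1	1	0	9
F3	0	0	1	1	1	1	1	1	0	0	6
F7	1	0	0	1	1	0	0	0	0	0	3
FT9	1	0	1	1	0	1	1	1	1	1	8
FC5	1	1	1	0	0	0	0	1	1	1	6
FC1	0	1	1	0	0	1	1	0	1	1	6
C3	1	1	1	0	1	1	0	1	1	1	8
T7	1	0	1	0	0	1	0	1	0	1	5
CP5	1	1	0	1	0	1	1	1	0	1	7
CP1	1	0	0	0	0	0	1	0	1	1	4
Pz	1	1	0	1	0	0	0	1	0	0	4
P3	1	1	1	0	1	0	0	1	0	1	6
P7	1	0	0	1	1	1	1	0	0	0	5
O1	1	0	1	1	1	0	0	0	1	1	6
Oz	0	1	0	1	1	1	0	1	1	1	7
O2	1	0	1	0	1	0	1	0	1	1	6
P4	0	1	0	1	1	0	0	1	1	0	5
P8	1	0	1	1	1	1	0	0	1	0	6
CP6	0	1	1	1	0	0	1	1	1	0	6
CP2	1	1	1	0	0	1	1	1	1	0	7
Cz	1	0	1	0	1	1	0	0	0	0	4
C4	0	0	0	1	0	1	0	1	0	0	3
T8	1	1	1	1	1	1	1	1	0	0	8
FT10	0	0	0	1	0	0	0	0	1	0	2
FC6	1	0	0	1	0	1	0	0	0	1	4
FC2	0	0	1	0	0	0	1	0	1	0	3
F4	1	0	1	1	1	0	0	1	0	1	6
F8	0	1	1	0	1	0	1	1	0	0	5
Fp2	0	1	1	0	0	0	1	0	0	0	3
Fz	1	0	1	0	0	0	0	1	1	0	4
Accuracy (%)	81.79	68.57	83.57	82.14	80.36	64.29	82.14	82.50	86.07	74.64	
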