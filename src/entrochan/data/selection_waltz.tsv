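Channel	1	6	7	12	13	18	19	24	25	30	Total
Fp1	0	1	1	1	0	0	1	1	0	0	5
F3	1	1	0	1	1	1	1	1	1	0	8
F7	1	0	1	1	1	0	0	1	1	0	6
FT9	1	0	1	0	0	1	1	0	0	1	5
FC5	0	0	1	0	0	0	0	0	1	1	3
FC1	1	0	0	1	0	1	0	0	1	0	4
C3	0	0	0	0	0	0	0	0	0	1	1
T7	1	1	1	1	0	0	1	0	0	0	5
CP5	0	1	1	0	1	1	1	0	1	1	7
CP1	1	0	1	1	1	0	0	0	1	1	6
Pz	1	1	1	1	1	1	1	1	1	1	10
P3	0	1	1	0	0	1	1	1	1	0	6
P7	1	0	1	1	1	1	0	0	1	1	7
O1	0	0	1	1	1	1	0	1	1	1	7
Oz	1	0	0	0	1	0	1	0	1	0	4
O2	1	0	1	1	0	0	1	1	1	0	6
P4	0	1	1	0	0	1	0	1	0	0	4
P8	1	1	1	1	0	0	0	1	0	0	5
CP6	1	1	0	0	0	1	0	0	1	1	5
CP2	1	1	1	1	1	1	0	1	0	0	7
Cz	0	1	1	1	0	0	1	1	0	0	5
C4	0	0	0	1	0	0	1	1	0	0	3
T8	1	0	1	1	1	1	1	1	0	1	8
FT10	1	0	0	1	1	1	0	0	0	0	4
FC6	0	0	0	1	0	0	1	1	0	1	4
FC2	1	1	0	0	1	1	1	0	1	1	7
F4	0	0	0	0	0	1	0	0	1	0	2
F8	1	1	1	0	1	1	1	0	1	1	8
Fp2	0	1	0	1	1	1	0	0	1	0	5
Fz	0	0	0	0	1	0	1	0	1	1	4
Accuracy (%)	81.47	82.69	84.66	84.12	83.70	82.21	68.84	70.53	82.15	83.20	
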