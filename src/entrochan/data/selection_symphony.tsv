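Channel	3	4	9	10	15	16	21	22	27	28	Total
Fp1	1	1	0	1	1	0	0	1	1	1	7
F3	1	1	0	1	0	1	1	1	0	1	7
F7	1	1	1	1	1	1	0	0	0	1	7
FT9	1	1	1	0	0	1	0	1	0	1	6
FC5	0	0	0	1	0	0	1	0	1	1	4
FC1	1	1	1	1	0	1	0	1	1	1	8
C3	0	0	0	0	1	1	0	0	1	1	4
T7	1	0	0	1	1	1	0	1	0	0	5
CP5	0	1	1	0	1	1	1	1	1	1	8
CP1	1	0	0	0	1	0	1	0	0	0	3
Pz	0	1	1	0	1	1	1	0	1	1	7
P3	1	1	1	1	1	0	0	1	1	0	7
P7	1	1	0	0	0	1	0	0	1	1	5
O1	1	0	1	0	1	1	1	0	1	1	7
Oz	1	1	0	0	0	1	1	1	0	1	6
O2	1	1	1	1	1	1	1	1	0	1	9
P4	1	0	1	1	1	1	0	0	1	0	6
P8	1	1	1	1	0	0	1	1	1	0	7
CP6	0	0	0	1	1	0	1	1	0	1	5
CP2	0	0	1	1	1	1	0	0	1	1	6
Cz	0	0	0	1	0	0	0	1	0	1	3
C4	0	1	1	0	1	0	0	1	1	0	5
T8	1	0	0	1	1	1	0	1	0	1	6
FT10	1	1	1	0	0	1	1	0	0	0	5
FC6	0	0	1	0	0	1	0	1	0	0	3
FC2	0	1	1	1	1	0	0	1	1	1	7
F4	1	0	1	1	1	1	0	0	0	0	5
F8	0	0	1	0	1	0	0	1	1	1	5
Fp2	1	0	0	1	1	0	1	0	1	1	6
Fz	1	0	1	0	1	1	0	1	0	1	6
Accuracy (%)	68.33	72.29	69.38	73.96	76.67	68.33	52.50	49.79	74.17	76.04	
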