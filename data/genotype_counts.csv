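variant,genotype,count
ABCB1_rs1045642,A/A,1
ABCB1_rs1045642,A/G,5
ABCB1_rs1045642,G/G,9
ABCC4_rs1751034,C/C,1
ABCC4_rs1751034,C/T,2
ABCC4_rs1751034,T/T,12
ABCC8_rs757110,A/A,3
ABCC8_rs757110,A/C,8
ABCC8_rs757110,C/C,4
ABCG2_rs2231142,G/G,8
ABCG2_rs2231142,G/T,6
ABCG2_rs2231142,T/T,1
UGT1A8_rs1042597,C/C,3
UGT1A8_rs1042597,C/G,4
UGT1A8_rs1042597,G/G,8
UGT2B15_rs1902023,A/A,7
UGT2B15_rs1902023,A/C,6
UGT2B15_rs1902023,C/C,2
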