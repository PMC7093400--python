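case_id,sex_age,deep_seated,engel,cds_region,cds_concordant,ecd_region,ecd_concordant,n_ied
1,F/19,1,I,L-CgG,1,L-SFG,0,21
2,F/27,1,I,L-Amy,1,L-BG,0,9
3,M/32,0,I,L-IC,0,NA,0,11
4,M/26,1,I,L-ScG,1,L-ScG,1,5
5,M/62,1,I,L-aITG,1,NA,0,5
6,M/12,1,I,L-Amy,1,NA,0,3
7,M/21,0,I,R-pITG,1,R-pITG,1,12
8,F/21,0,I,R-SFG,1,R-MFG,1,5
9,F/11,1,I,R-aITG,1,NA,0,13
10,F/44,1,I,R-FuG,0,R-SFG,0,12
11,F/16,0,I,R-aMTG,1,R-FuG,1,8
12,M/15,0,I,L-aMTG,1,L-IFG,0,12
13,M/30,1,I,L-PHG,1,L-aMTG,0,12
14,M/44,1,II,L-aMTG,0,L-CC,0,20
15,M/40,1,II,R-Hip,1,NA,0,15
16,F/20,0,II,L-pMTG,0,NA,0,9
17,M/8,0,II,R-ScG,0,R-pSTG,1,6
18,M/56,0,III,R-Hip,0,NA,0,12
19,M/21,1,III,L-OFG,1,L-FP,0,16
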