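cns,prednisone,day33_m,mrd_category,workflow,risk
CNS1,GOOD,M1,,ORIGINAL,LR
CNS1,GOOD,M1,NEG_LT_0.01,UPDATED,VLR
CNS1,GOOD,M1,POS_0.01_0.1,UPDATED,LR
CNS1,GOOD,M1,POS_0.1_10,UPDATED,IR
CNS1,GOOD,M1,POS_GT_10,UPDATED,HR
CNS1,GOOD,M2,,ORIGINAL,HR
CNS1,GOOD,M2,NEG_LT_0.01,UPDATED,HR
CNS1,GOOD,M2,POS_0.01_0.1,UPDATED,HR
CNS1,GOOD,M2,POS_0.1_10,UPDATED,HR
CNS1,GOOD,M2,POS_GT_10,UPDATED,HR
CNS1,GOOD,M3,,ORIGINAL,HR
CNS1,GOOD,M3,NEG_LT_0.01,UPDATED,HR
CNS1,GOOD,M3,POS_0.01_0.1,UPDATED,HR
CNS1,GOOD,M3,POS_0.1_10,UPDATED,HR
CNS1,GOOD,M3,POS_GT_10,UPDATED,HR
CNS1,POOR,M1,,ORIGINAL,HR
CNS1,POOR,M1,NEG_LT_0.01,UPDATED,HR
CNS1,POOR,M1,POS_0.01_0.1,UPDATED,HR
CNS1,POOR,M1,POS_0.1_10,UPDATED,HR
CNS1,POOR,M1,POS_GT_10,UPDATED,HR
CNS1,POOR,M2,,ORIGINAL,HR
CNS1,POOR,M2,NEG_LT_0.01,UPDATED,HR
CNS1,POOR,M2,POS_0.01_0.1,UPDATED,HR
CNS1,POOR,M2,POS_0.1_10,UPDATED,HR
CNS1,POOR,M2,POS_GT_10,UPDATED,HR
CNS1,POOR,M3,,ORIGINAL,HR
CNS1,POOR,M3,NEG_LT_0.01,UPDATED,HR
CNS1,POOR,M3,POS_0.01_0.1,UPDATED,HR
CNS1,POOR,M3,POS_0.1_10,UPDATED,HR
CNS1,POOR,M3,POS_GT_10,UPDATED,HR
CNS2,GOOD,M1,,ORIGINAL,IR
CNS2,GOOD,M1,NEG_LT_0.01,UPDATED,IR
CNS2,GOOD,M1,POS_0.01_0.1,UPDATED,IR
CNS2,GOOD,M1,POS_0.1_10,UPDATED,IR
CNS2,GOOD,M1,POS_GT_10,UPDATED,HR
CNS2,GOOD,M2,,ORIGINAL,HR
CNS2,GOOD,M2,NEG_LT_0.01,UPDATED,HR
CNS2,GOOD,M2,POS_0.01_0.1,UPDATED,HR
CNS2,GOOD,M2,POS_0.1_10,UPDATED,HR
CNS2,GOOD,M2,POS_GT_10,UPDATED,HR
CNS2,GOOD,M3,,ORIGINAL,HR
CNS2,GOOD,M3,NEG_LT_0.01,UPDATED,HR
CNS2,GOOD,M3,POS_0.01_0.1,UPDATED,HR
CNS2,GOOD,M3,POS_0.1_10,UPDATED,HR
CNS2,GOOD,M3,POS_GT_10,UPDATED,HR
CNS2,POOR,M1,,ORIGINAL,HR
CNS2,POOR,M1,NEG_LT_0.01,UPDATED,HR
CNS2,POOR,M1,POS_0.01_0.1,UPDATED,HR
CNS2,POOR,M1,POS_0.1_10,UPDATED,HR
CNS2,POOR,M1,POS_GT_10,UPDATED,HR
CNS2,POOR,M2,,ORIGINAL,HR
CNS2,POOR,M2,NEG_LT_0.01,UPDATED,HR
CNS2,POOR,M2,POS_0.01_0.1,UPDATED,HR
CNS2,POOR,M2,POS_0.1_10,UPDATED,HR
CNS2,POOR,M2,POS_GT_10,UPDATED,HR
CNS2,POOR,M3,,ORIGINAL,HR
CNS2,POOR,M3,NEG_LT_0.01,UPDATED,HR
CNS2,POOR,M3,POS_0.01_0.1,UPDATED,HR
CNS2,POOR,M3,POS_0.1_10,UPDATED,HR
CNS2,POOR,M3,POS_GT_10,UPDATED,HR
CNS3,GOOD,M1,,ORIGINAL,HR
CNS3,GOOD,M1,NEG_LT_0.01,UPDATED,HR
CNS3,GOOD,M1,POS_0.01_0.1,UPDATED,HR
CNS3,GOOD,M1,POS_0.1_10,UPDATED,HR
CNS3,GOOD,M1,POS_GT_10,UPDATED,HR
CNS3,GOOD,M2,,ORIGINAL,HR
CNS3,GOOD,M2,NEG_LT_0.01,UPDATED,HR
CNS3,GOOD,M2,POS_0.01_0.1,UPDATED,HR
CNS3,GOOD,M2,POS_0.1_10,UPDATED,HR
CNS3,GOOD,M2,POS_GT_10,UPDATED,HR
CNS3,GOOD,M3,,ORIGINAL,HR
CNS3,GOOD,M3,NEG_LT_0.01,UPDATED,HR
CNS3,GOOD,M3,POS_0.01_0.1,UPDATED,HR
CNS3,GOOD,M3,POS_0.1_10,UPDATED,HR
CNS3,GOOD,M3,POS_GT_10,UPDATED,HR
CNS3,POOR,M1,,ORIGINAL,HR
CNS3,POOR,M1,NEG_LT_0.01,UPDATED,HR
CNS3,POOR,M1,POS_0.01_0.1,UPDATED,HR
CNS3,POOR,M1,POS_0.1_10,UPDATED,HR
CNS3,POOR,M1,POS_GT_10,UPDATED,HR
CNS3,POOR,M2,,ORIGINAL,HR
CNS3,POOR,M2,NEG_LT_0.01,UPDATED,HR
CNS3,POOR,M2,POS_0.01_0.1,UPDATED,HR
CNS3,POOR,M2,POS_0.1_10,UPDATED,HR
CNS3,POOR,M2,POS_GT_10,UPDATED,HR
CNS3,POOR,M3,,ORIGINAL,HR
CNS3,POOR,M3,NEG_LT_0.01,UPDATED,HR
CNS3,POOR,M3,POS_0.01_0.1,UPDATED,HR
CNS3,POOR,M3,POS_0.1_10,UPDATED,HR
CNS3,POOR,M3,POS_GT_10,UPDATED,HR
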