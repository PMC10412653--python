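# iopn-tme/cohort-table-v1
# 15-case pancreatic IOPN cohort: clinicopathologic features and IHC results.
# Scores are the semi-quantitative 0-5 per-HPF values; TPS in %, CPS capped at 100.
# *_inv columns carry the invasive-component values of the two invasive cases
# (reported in brackets in the source table); blank where no invasive component.
# MMR columns: retained / loss. Note: the published cohort-mean age (61.6) is the
# truncated, not rounded, value of the column mean (61.666...).
id,gender,age_years,size_cm,size_cm_inv,duct_type,site,pTNM,CD3,CD4,CD8,CD20,PD1,TPS,CPS,CD68,CD163,CD3_inv,CD4_inv,CD8_inv,CD20_inv,PD1_inv,TPS_inv,CPS_inv,CD68_inv,CD163_inv,MLH1,PMS2,MSH2,MSH6
1,M,63,2,,Mx,H,pTis,5,4,5,2,2,5,5,4,3,,,,,,,,,,retained,retained,retained,retained
2,M,41,14,,Mx,B,pTis,5,4,5,1,3,0,0,4,3,,,,,,,,,,retained,retained,retained,retained
3,M,80,4,,Mx,H,pTis,5,4,5,2,5,0,0,3,3,,,,,,,,,,retained,retained,retained,retained
4,M,56,5,,Mx,H,pTis,5,3,5,4,5,50,55,3,3,,,,,,,,,,retained,retained,retained,retained
5,F,65,3.5,,MD,B,pTis,4,1,4,0,1,0,0,2,2,,,,,,,,,,retained,retained,retained,retained
6,M,80,5,,Mx,H,pTis,5,4,4,1,3,0,5,3,2,,,,,,,,,,retained,retained,retained,retained
7,M,60,5,,Mx,B,pTis,5,3,5,2,5,10,12,4,3,,,,,,,,,,retained,retained,retained,retained
8,M,46,6,,Mx,T,pTis,5,3,4,2,4,20,22,3,3,,,,,,,,,,retained,retained,retained,retained
9,F,68,4,,Mx,H,pTis,4,2,3,0,1,0,0,4,4,,,,,,,,,,retained,retained,retained,retained
10,F,68,2,,Mx,B,pTis,5,3,3,4,3,5,5,4,4,,,,,,,,,,retained,retained,retained,retained
11,M,65,8,,Mx,H,pTis,4,2,3,3,5,60,65,4,3,,,,,,,,,,retained,retained,retained,retained
12,M,63,5,,MD,B-T,pTis,5,3,4,1,4,0,0,3,3,,,,,,,,,,retained,retained,retained,retained
13,M,48,5,,Mx,H,pTis,5,3,4,3,5,2,10,3,2,,,,,,,,,,retained,retained,retained,retained
14,M,62,3,1,BD,H,T1cN0M0,4,3,4,1,2,0,5,2,2,5,2,5,1,3,0,20,5,5,retained,retained,retained,retained
15,M,60,6,3,BD,B,T2N0M0,3,4,3,2,1,0,0,4,3,5,2,5,2,4,5,7,5,5,retained,retained,retained,retained
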