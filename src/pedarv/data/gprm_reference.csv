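drug,strength,scope,gprm_monthly_cost
ABC,20 mg/ml,pediatric,15.84
ABC,60 mg,pediatric,12.36
d4T,1 mg/ml,pediatric,4.56
d4T,15 mg,pediatric,1.44
3TC,10 mg/ml,pediatric,2.06
LPV/r,80/20 mg/ml,pediatric,11.81
LPV/r,100/25 mg,pediatric,11.20
NVP,10 mg/ml,pediatric,4.81
NVP,50 mg,pediatric,N/A
ZDV,10 mg/ml,pediatric,4.82
ZDV,60 mg,pediatric,N/A
ZDV/3TC,60/30 mg,pediatric,5.60
ZDV/3TC/NVP,60/30/50 mg,pediatric,8.28
d4T/3TC,6/30 mg,pediatric,3.79
d4T/3TC/NVP,6/30/50 mg,pediatric,4.66
ABC/3TC,60/30 mg,pediatric,13.96
ABC,300 mg,adult,13.39
d4T,30 mg,adult,1.52
3TC,150 mg,adult,2.36
EFV,600 mg,adult,3.86
LPV/r,200/50 mg,adult,29.47
NVP,200 mg,adult,2.47
ZDV,300 mg,adult,6.98
ZDV/3TC,300/150 mg,adult,7.86
ZDV/3TC/NVP,300/150/200 mg,adult,9.89
d4T/3TC,30/150 mg,adult,2.99
d4T/3TC/NVP,30/150/200 mg,adult,4.76
ABC/3TC,600/300 mg,adult,22.56
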