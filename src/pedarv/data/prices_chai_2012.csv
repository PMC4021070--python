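drug,strength,unit_cost,unit_cost_high
ABC,20 mg/ml,0.06,
ABC,60 mg,0.09,
ABC,300 mg,0.26,
d4T,1 mg/ml,0.01,
d4T,15 mg,0.02,
d4T,20 mg,0.02,
d4T,30 mg,0.03,
3TC,10 mg/ml,0.01,
3TC,150 mg,0.04,
EFV,200 mg,0.11,
EFV,600 mg,0.15,
LPV/r,80/20 mg/ml,0.19,
LPV/r,100/25 mg,0.14,
LPV/r,200/50 mg,0.26,
NVP,10 mg/ml,0.01,
NVP,50 mg,0.045,
NVP,200 mg,0.05,
ZDV,10 mg/ml,0.01,
ZDV,60 mg,0.05,
ZDV,300 mg,0.12,
ZDV/3TC,60/30 mg,0.05,
ZDV/3TC,300/150 mg,0.15,
ZDV/3TC/NVP,60/30/50 mg,0.07,
ZDV/3TC/NVP,300/150/200 mg,0.19,
d4T/3TC,6/30 mg,0.03,
d4T/3TC,30/150 mg,0.06,
d4T/3TC/NVP,6/30/50 mg,0.04,
d4T/3TC/NVP,30/150/200 mg,0.11,
ABC/3TC,60/30 mg,0.09,
ABC/3TC,600/300 mg,0.583,1.07
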