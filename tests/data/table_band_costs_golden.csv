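drug,strength,3-5.9 kg,6-9.9 kg,10-13.9 kg,14-19.9 kg,20-24.9 kg,25-34.9 kg,35+ kg
ABC,20 mg/ml,10.94,14.59,21.89,,,,
ABC,60 mg,5.47,8.21,10.94,13.68,16.42,,
ABC,300 mg,,,,,,15.81,15.81
d4T,1 mg/ml,3.65,5.47,,,,,
d4T,15 mg,,,1.22,,,,
d4T,20 mg,,,,1.22,1.22,,
d4T,30 mg,,,,,,1.82,1.82
3TC,10 mg/ml,1.82,2.43,3.65,,,,
3TC,150 mg,,,,1.22,1.82,2.43,2.43
EFV,200 mg,NR,NR,3.34,5.02,5.02,6.69,
EFV,600 mg,,,,,,,4.56
LPV/r,80/20 mg/ml,11.55,17.33,23.10,28.88,34.66,,
LPV/r,100/25 mg,NR,NR,12.77,17.02,17.02,25.54,
LPV/r,200/50 mg,,,,,,,31.62
NVP,10 mg/ml,3.04,4.86,6.08,,,,
NVP,50 mg,2.74,4.10,5.47,6.84,8.21,,
NVP,200 mg,,,,,,3.04,3.04
ZDV,10 mg/ml,3.65,5.47,7.30,,,,
ZDV,60 mg,3.04,4.56,6.08,7.60,9.12,,
ZDV,300 mg,,,,,,7.30,7.30
ZDV/3TC,60/30 mg,3.04,4.56,6.08,7.60,9.12,,
ZDV/3TC,300/150 mg,,,,,,9.12,9.12
ZDV/3TC/NVP,60/30/50 mg,4.26,6.38,8.51,10.64,12.77,,
ZDV/3TC/NVP,300/150/200 mg,,,,,,11.55,11.55
d4T/3TC,6/30 mg,1.82,2.74,3.65,4.56,5.47,,
d4T/3TC,30/150 mg,,,,,,3.65,3.65
d4T/3TC/NVP,6/30/50 mg,2.43,3.65,4.86,6.08,7.30,,
d4T/3TC/NVP,30/150/200 mg,,,,,,6.69,6.69
ABC/3TC,60/30 mg,5.47,8.21,10.94,13.68,16.42,,
ABC/3TC,600/300 mg,,,,,,17.72-32.53,17.72-32.53
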