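trait,treatment,mean,sd,cv,min,max,suspect
DSG,T0,5.56,1.067,19.17,4,9,
DSG,T1,8.78,1.467,16.70,5,14,
DSG,T2,12.05,1.736,14.41,7,16,
NOL,T0,4.06,0.754,18.56,3,7,
NOL,T1,3.28,0.740,22.59,2,5,
NOL,T2,2.56,0.720,28.10,1,5,
TFW,T0,0.59,0.157,26.61,0.29,0.88,
TFW,T1,0.48,0.149,30.88,0.07,0.78,
TFW,T2,0.35,0.135,38.05,0.05,0.59,
TDW,T0,0.17,0.055,33.11,0.06,0.27,
TDW,T1,0.14,0.043,32.23,0.02,0.2,
TDW,T2,0.09,0.038,40.07,0.01,0.17,
SR,T0,0.72,0.095,13.08,0.53,0.93,
SR,T1,0.48,0.122,25.45,0.27,0.87,
SR,T2,0.21,0.186,86.65,0.07,0.8,
NSR,T0,18.54,4.278,23.08,9,32,
NSR,T1,14.29,5.419,37.93,4,35,
NSR,T2,8.90,4.011,45.07,4,24,
RL,T0,6.14,0.793,12.93,4.4,8.1,
RL,T1,5.60,1.495,26.68,3.9,11.2,
RL,T2,4.86,1.310,26.99,2.7,9.2,
SL,T0,8.27,1.039,12.57,6,4.4,yes
SL,T1,7.31,2.114,28.91,4.7,12.1,
SL,T2,5.87,1.601,27.29,3.4,7,
RFW,T0,0.053,0.012,22.06,0.018,0.077,
RFW,T1,0.046,0.017,37.53,0.014,0.096,
RFW,T2,0.043,0.051,120.10,0.01,0.4,
R/S,T0,0.75,0.074,9.98,0.58,0.88,
R/S,T1,0.77,0.079,10.21,0.61,0.92,
R/S,T2,0.83,0.082,9.83,0.67,0.98,
Chla,T0,4.24,1.646,38.83,1.309,8.81,
Chla,T1,5.14,1.422,27.67,2.124,8.024,
Chla,T2,6.28,1.890,30.13,2.632,9.45,
Chlb,T0,3.09,1.803,58.23,0.44,7.71,
Chlb,T1,3.79,1.461,38.45,1.14,7.73,
Chlb,T2,5.14,1.854,36.1,1.55,7.95,
TChl,T0,7.34,3.084,42.03,1.75,15.24,
TChl,T1,8.94,2.419,27.07,3.58,13,
TChl,T2,11.41,3.475,30.45,4.18,16.99,
CAR,T0,1.94,0.959,49.59,0.18,3.99,
CAR,T1,2.49,0.798,32.04,0.49,3.69,
CAR,T2,3.12,1.080,34.57,0.14,4.96,
Pro,T0,5.61,0.611,10.89,4.52,7.21,
Pro,T1,17.65,4.542,25.74,9.08,27.97,
Pro,T2,29.09,8.784,30.2,12.19,50.03,
MDA,T0,2.07,0.571,27.56,1.10,3.34,
MDA,T2,8.55,2.070,24.20,5.60,13.68,
H2O2,T0,12.09,1.55,12.88,9.67,15.74,
H2O2,T2,32.29,7.25,22.46,19.89,46.52,
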