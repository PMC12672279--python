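genotype,SSI,MPI,GMPI,HMI,STI,TI,SI,STS
G1,0.859,0.165,0.027,0.163,0.969,0.037,0.800,3.019
G2,0.909,0.153,0.023,0.150,0.828,0.047,0.736,2.845
G3,0.824,0.165,0.026,0.160,0.952,0.057,0.707,2.891
G4,0.695,0.182,0.031,0.169,1.105,0.097,0.580,2.858
G5,0.668,0.190,0.034,0.179,1.223,0.093,0.606,2.992
G6,0.713,0.185,0.033,0.178,1.189,0.070,0.682,3.050
G7,0.756,0.175,0.029,0.168,1.060,0.070,0.667,2.924
G8,1.079,0.128,0.016,0.123,0.571,0.050,0.674,2.642
G9,1.078,0.137,0.019,0.135,0.667,0.027,0.822,2.885
G10,0.674,0.195,0.037,0.189,1.326,0.070,0.696,3.186
G11,0.773,0.165,0.025,0.153,0.908,0.090,0.571,2.686
G12,0.772,0.150,0.018,0.117,0.634,0.140,0.364,2.195
G13,0.803,0.165,0.026,0.158,0.937,0.070,0.650,2.808
G14,0.610,0.200,0.036,0.182,1.312,0.120,0.538,2.999
G15,0.730,0.160,0.021,0.129,0.746,0.140,0.391,2.317
G16,0.919,0.142,0.019,0.131,0.670,0.077,0.574,2.532
G17,0.999,0.125,0.014,0.109,0.490,0.090,0.471,2.297
G18,0.812,0.160,0.024,0.150,0.865,0.080,0.600,2.691
G19,0.679,0.165,0.020,0.121,0.721,0.170,0.320,2.196
G20,0.903,0.130,0.013,0.102,0.479,0.120,0.368,2.117
G21,1.242,0.108,0.011,0.101,0.394,0.057,0.585,2.498
G22,1.348,0.090,0.007,0.072,0.234,0.080,0.385,2.216
G23,1.028,0.127,0.015,0.116,0.530,0.073,0.551,2.440
G24,1.213,0.110,0.011,0.102,0.404,0.060,0.571,2.471
G25,0.738,0.170,0.026,0.155,0.951,0.100,0.545,2.687
G42,1.832,0.083,0.007,0.082,0.247,0.020,0.786,3.057
G43,1.737,0.093,0.009,0.093,0.314,0.007,0.931,3.184
G44,1.531,0.087,0.007,0.078,0.245,0.053,0.529,2.530
G45,1.694,0.118,0.013,0.113,0.482,-0.050,1.536,3.906
G46,1.340,0.103,0.010,0.098,0.365,0.047,0.632,2.595
G47,1.918,0.062,0.003,0.045,0.101,0.063,0.321,2.513
G48,1.714,0.072,0.004,0.058,0.149,0.063,0.387,2.447
G49,0.845,0.130,0.011,0.085,0.397,0.153,0.258,1.880
G51,1.504,0.107,0.011,0.107,0.410,0.007,0.939,3.085
G53,2.253,0.052,0.002,0.036,0.067,0.057,0.292,2.758
G54,1.743,0.092,0.008,0.091,0.302,0.010,0.897,3.143
G55,2.722,0.042,0.001,0.027,0.040,0.050,0.250,3.131
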