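genotype,SSI,MPI,GMPI,HMI,STI,TI,SI,STS
G1,0.842,0.173,0.030,0.173,1.079,0.020,0.891,3.208
G2,0.874,0.170,0.029,0.170,1.040,0.013,0.925,3.220
G3,0.799,0.178,0.032,0.177,1.138,0.030,0.845,3.198
G4,0.663,0.202,0.040,0.198,1.437,0.057,0.754,3.350
G5,0.652,0.200,0.039,0.193,1.393,0.073,0.690,3.241
G6,0.682,0.203,0.041,0.202,1.480,0.033,0.848,3.490
G7,0.723,0.193,0.037,0.192,1.337,0.033,0.841,3.357
G8,1.051,0.140,0.019,0.139,0.700,0.027,0.826,2.902
G9,1.013,0.163,0.027,0.162,0.955,-0.027,1.178,3.471
G10,0.653,0.208,0.043,0.206,1.547,0.043,0.812,3.512
G11,0.721,0.195,0.038,0.194,1.362,0.030,0.857,3.397
G12,0.733,0.173,0.028,0.161,1.004,0.093,0.576,2.768
G13,0.775,0.180,0.032,0.178,1.153,0.040,0.800,3.158
G14,0.575,0.225,0.049,0.220,1.780,0.070,0.731,3.650
G15,0.679,0.192,0.035,0.184,1.271,0.077,0.667,3.105
G16,0.882,0.160,0.025,0.158,0.908,0.040,0.778,2.950
G17,0.952,0.147,0.021,0.143,0.756,0.047,0.725,2.790
G18,0.766,0.185,0.034,0.184,1.225,0.030,0.850,3.274
G19,0.618,0.207,0.041,0.198,1.472,0.087,0.653,3.274
G20,0.864,0.150,0.021,0.139,0.753,0.080,0.579,2.587
G21,1.206,0.122,0.015,0.120,0.525,0.030,0.780,2.798
G22,1.287,0.112,0.012,0.109,0.437,0.037,0.718,2.711
G23,0.994,0.142,0.020,0.138,0.706,0.043,0.735,2.778
G24,1.173,0.125,0.015,0.123,0.555,0.030,0.786,2.807
G25,0.702,0.192,0.036,0.187,1.295,0.057,0.742,3.211
G42,1.819,0.087,0.007,0.086,0.269,0.013,0.857,3.139
G43,1.680,0.108,0.012,0.107,0.418,-0.023,1.241,3.543
G44,1.487,0.100,0.010,0.098,0.354,0.027,0.765,2.841
G45,1.601,0.142,0.018,0.125,0.639,-0.097,2.036,4.464
G46,1.306,0.115,0.013,0.114,0.472,0.023,0.816,2.859
G47,1.832,0.083,0.007,0.082,0.247,0.020,0.786,3.057
G48,1.625,0.097,0.009,0.096,0.335,0.013,0.871,3.047
G49,0.810,0.150,0.019,0.129,0.695,0.113,0.452,2.368
G51,1.353,0.152,0.021,0.140,0.766,-0.083,1.758,4.107
G53,2.214,0.060,0.003,0.053,0.115,0.040,0.500,2.986
G54,1.686,0.107,0.011,0.106,0.406,-0.020,1.207,3.503
G55,2.694,0.047,0.002,0.038,0.064,0.040,0.400,3.285
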