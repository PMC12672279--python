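genotype,category_T0,total_T0,category_T1,total_T1,category_T2,total_T2,overall
G1,M,29,M,31,M,31,91
G2,M,29,M,31,M,30,90
G3,M,31,M,28,I,26,85
G4,M,29,M,29,M,30,88
G5,I,27,I,25,M,30,82
G6,E,36,E,35,E,37,108
G7,M,31,M,33,E,34,98
G8,I,27,I,26,M,29,82
G9,M,32,M,29,E,34,95
G10,E,38,E,35,M,33,106
G11,M,30,M,31,M,28,89
G12,M,28,I,26,I,26,80
G13,M,30,M,32,M,31,93
G14,M,31,M,28,M,29,88
G15,M,28,M,31,M,28,87
G16,M,31,M,28,I,25,84
G17,M,28,M,29,M,29,86
G18,M,31,M,30,M,31,92
G19,M,28,M,28,M,33,89
G20,M,29,M,29,M,29,87
G21,M,30,M,27,M,30,87
G22,M,30,M,27,M,31,88
G23,M,28,M,33,E,35,96
G24,M,30,M,31,M,31,92
G25,M,29,M,30,M,29,88
G42,M,30,M,29,M,28,87
G43,E,35,M,30,M,29,94
G44,M,32,M,33,M,32,97
G45,M,31,E,37,E,34,102
G46,M,32,M,30,M,30,92
G47,M,28,I,26,I,26,80
G48,M,28,M,30,M,28,86
G49,I,27,M,30,M,31,88
G51,E,35,E,38,E,35,108
G53,M,29,I,25,M,29,83
G54,M,30,E,34,E,34,98
G55,I,27,I,24,M,29,80
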