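pop,AJAR,ARM,BLK,CHCHN,IMR,KAKH,KHEVS,KRCH,KRT,LAZ,MSKH,SMG,SVN,TUSH
AJAR,0,0.003,0.005,0.008,0.001,0.002,0.021,0.007,0,0.003,0.008,0,0.003,0.013
ARM,4.356,0,0.007,0.01,0.005,0.002,0.024,0.01,0.003,0.006,0.007,0.005,0.01,0.016
BLK,5.486,9.999,0,0.007,0.005,0.004,0.022,0.003,0.004,0.008,0.011,0.004,0.007,0.015
CHCHN,9.999,9.999,9.999,0,0.009,0.007,0.024,0.01,0.007,0.012,0.014,0.009,0.012,0.016
IMR,1.029,9.392,6.495,9.999,0,0.001,0.021,0.007,0.001,0.004,0.009,0,0.004,0.014
KAKH,2.132,4.09,5.567,9.999,1.342,0,0.018,0.006,-0.001,0.004,0.006,0.001,0.005,0.011
KHEVS,9.999,9.999,9.999,9.999,9.999,9.999,0,0.026,0.016,0.025,0.027,0.022,0.025,0.013
KRCH,6.567,9.999,3.412,9.999,8.028,7.128,9.999,0,0.007,0.012,0.015,0.007,0.009,0.017
KRT,0.241,5.725,6.815,9.999,1.024,-2.523,9.999,7.993,0,0.003,0.007,0.001,0.005,0.01
LAZ,4.205,9.999,9.999,9.999,9.077,8.666,9.999,9.999,9.248,0,0.011,0.004,0.008,0.017
MSKH,9.124,9.999,9.999,9.999,9.999,9.811,9.999,9.999,9.999,9.999,0,0.009,0.014,0.02
SMG,0.506,9.887,5.304,9.999,0.362,2.053,9.999,7.464,2.188,8.597,9.999,0,0.003,0.015
SVN,3.725,9.999,9.835,9.999,6.879,8.708,9.999,9.611,8.318,9.999,9.999,4.178,0,0.017
TUSH,9.999,9.999,9.999,9.999,9.999,9.999,9.999,9.999,9.999,9.999,9.999,9.999,9.999,0
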