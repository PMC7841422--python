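tissue_name,V_T,f_EW,f_IW,f_NL,f_NP,AP,RA_alb,RA_lip,pH_IW
adipose,0.2000,0.135,0.017,0.846,0.0016,0.40,0.049,0.068,7.0
bone,0.1500,0.100,0.346,0.017,0.0017,0.67,0.100,0.050,7.0
brain,0.0207,0.162,0.620,0.039,0.0015,0.40,0.048,0.041,7.0
gut,0.0171,0.282,0.475,0.038,0.0125,2.41,0.158,0.141,7.0
heart,0.0047,0.320,0.456,0.014,0.0111,2.25,0.157,0.160,7.0
kidney,0.0044,0.273,0.483,0.012,0.0242,5.03,0.130,0.137,7.0
liver,0.0257,0.161,0.573,0.014,0.0240,4.56,0.086,0.161,7.0
lung,0.0076,0.336,0.446,0.022,0.0128,3.91,0.212,0.168,7.0
muscle,0.4000,0.118,0.630,0.010,0.0072,1.53,0.064,0.059,7.0
pancreas,0.0020,0.120,0.664,0.041,0.0093,1.67,0.060,0.060,7.0
skin,0.0470,0.382,0.291,0.060,0.0044,1.32,0.277,0.096,7.0
spleen,0.0021,0.207,0.579,0.0077,0.0113,3.18,0.097,0.207,7.0
thymus,0.0003,0.150,0.626,0.017,0.0092,2.30,0.075,0.075,7.0
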