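depth_m,temp_C,pH,alk_mgL,F_mgL,Cl_mgL,Br_mgL,P_mgL,NO3_mgL,SO4_mgL,Ca_mgL,Mg_mgL,Na_mgL,K_mgL,NH4_mgL,Li_mgL,S2_mgL,Fe_mgL,Mn_mgL,Zn_mgL,TDS_mgL,d13C_TDIC_calc,d13C_TDIC,dD_H2O,d18O_H2O
0,26.6,9.29,403,10.7,549,1.5,<0.0005,0.24,200,18,16,512,65,2.2,0.72,,0.011,<0.0005,0.0063,1779,,-2.91,-13.08,-1.35
2,26.6,9.28,395,9.8,546,1.5,<0.0005,0.12,202,17,15,521,66,2.3,0.76,0.41,0.0056,<0.0005,0.0062,1777,,-2.78,-12.58,-1.28
4,24.3,9.14,413,10.1,537,1.5,<0.0005,0.11,197,17,12,502,68,1.9,0.61,,0.0027,<0.0005,0.0028,1761,,-2.95,-12.07,-1.07
6,15.0,8.53,417,9.89,535,1.5,<0.0005,0.072,195,24,13,484,57,2.3,0.56,0.87,0.015,0.0011,0.0030,1740,-2.9,-3.02,-12.55,-1.05
8,11.7,7.83,427,10.6,540,1.5,<0.0005,0.24,194,26,12,483,51,1.7,0.55,,0.0012,0.0045,0.012,1748,-2.9,-3.11,-12.71,-1.14
10,11.2,7.82,429,10.5,548,1.5,<0.0005,1.1,194,30,14,483,55,1.5,0.48,2.5,0.00031,0.017,0.0022,1770,-3.8,-3.56,-12.39,-1.15
12,11.3,7.81,419,9.64,536,1.6,<0.0005,1.2,195,29,13,490,50,2.3,0.58,,0.00029,0.0036,0.0013,1747,-3.4,-4.11,-12.11,-1.11
14,10.9,7.80,419,10.3,542,1.6,<0.0005,0.38,197,31,13,474,53,2.4,0.72,2.7,0.00025,0.0084,0.0017,1747,-2.8,-4.39,-11.54,-1.05
16,10.8,7.78,416,10.5,539,2.0,<0.0005,0.27,195,30,13,479,52,1.6,0.69,,0.00027,0.031,0.0013,1739,-3.0,-4.87,-11.89,-1.19
18,10.7,7.67,415,10.1,541,1.5,<0.0005,0.082,195,32,14,482,52,3.8,0.47,4.6,0.00083,0.10,0.0014,1753,-1.7,-5.06,-12.41,-1.12
20,10.7,7.53,411,10.0,550,1.6,0.001,0.38,197,32,14,485,55,3.9,0.66,7.9,0.010,0.41,0.0031,1768,-4.6,-4.91,-12.08,-1.25
22,10.8,7.38,426,9.94,567,1.5,0.002,0.35,199,36,14,499,56,4.3,0.73,8.3,0.028,0.59,0.0004,1821,-3.6,-4.11,-12.63,-1.22
24,10.8,7.23,460,10.1,592,1.6,0.004,0.17,203,40,17,510,57,7.7,0.85,,0.036,0.59,0.021,1899,-3.6,-4.25,-11.85,-1.31
26,10.9,7.12,586,9.74,632,1.8,0.009,0.16,195,49,18,550,57,13,0.62,8.5,0.041,0.52,0.0022,2121,-2.9,-3.61,-12.12,-1.14
28,10.9,7.02,676,9.90,680,1.8,0.014,0.13,197,59,19,576,62,16,0.82,,0.036,0.45,0.0024,2297,-1.9,-3.66,-12.57,-1.19
30,10.9,6.97,761,10.0,706,2.0,0.018,0.16,191,63,20,592,64,22,0.51,13,0.034,0.42,0.0011,2445,-4.2,-3.51,-13.05,-1.07
32,11.0,6.89,814,10.2,730,2.1,0.021,0.11,191,70,22,622,66,25,0.60,13,0.031,0.40,0.0010,2565,-1.4,-4.85,-12.01,-1.26
34,10.8,6.73,944,10.7,783,2.2,0.031,0.07,185,83,27,645,72,36,0.45,18,0.055,0.41,0.0038,2805,-2.2,-5.08,-11.53,-1.11
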