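depth_m,PCO2_atm,PN2_atm,PAr_atm,PCH4_atm,PO2_atm,PH2_atm,PHe_atm,pTOT_atm,d13C_CO2,d13C_CH4,dD_CH4,PCO2calc_atm
0,0.000026,0.76,0.0090,,0.14,,0.000005,0.90,,,,0.00018
2,0.000030,0.74,0.0085,,0.14,,0.000005,0.88,,,,0.00018
4,0.000082,0.72,0.0085,,0.16,,0.000006,0.88,,,,0.00027
6,0.00013,0.62,0.0073,,0.20,,0.000008,0.83,-11.9,,,0.0014
8,0.00028,0.60,0.0069,,0.22,,0.000005,0.82,-12.3,,,0.0077
10,0.00070,0.57,0.0066,0.000026,0.13,,0.000008,0.71,-13.2,-50.7,,0.0080
12,0.0014,0.57,0.0065,0.00029,0.029,,0.000010,0.60,-12.8,-53.1,-267,0.0080
14,0.0047,0.57,0.0066,0.00073,,0.00023,0.000007,0.58,-12.0,-53.6,-271,0.0083
16,0.0048,0.56,0.0065,0.0016,,0.00058,0.000015,0.57,-12.2,-54.1,-269,0.0086
18,0.0075,0.56,0.0063,0.0045,,0.00092,0.000020,0.69,-10.6,-54.7,-272,0.011
20,0.010,0.57,0.0065,0.024,,0.0013,0.000020,0.67,-13.3,-56.9,-275,0.015
22,0.015,0.56,0.0064,0.052,,0.0022,0.000027,0.64,-12.1,-58.1,-270,0.022
24,0.025,0.57,0.0063,0.10,,0.0033,0.000037,0.70,-11.5,-59.5,-269,0.034
26,0.030,0.57,0.0065,0.19,,0.0054,0.000052,0.80,-10.9,-62.2,-275,0.055
28,0.053,0.58,0.0063,0.30,,0.0073,0.000062,0.94,-9.2,-63.4,-272,0.079
30,0.065,0.58,0.0062,0.47,,0.0075,0.000065,1.12,-11.3,-65.2,-268,0.100
32,0.085,0.58,0.0062,0.50,,0.010,0.000077,1.18,-8.2,-65.1,-271,0.13
34,0.093,0.59,0.0061,0.64,,0.013,0.000095,1.33,-9.1,-65.4,-269,0.21
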