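sample_id,place,raw_material,year,reported_abv,measured_abv,price_eur_per_l,Al,Cu,Fe,Mn,Ni,Pb,Zn
Sample 1,Producer's home,Grape,2019,,42.3,3.5,0.068,18.221,0.205,0.014,<LOD,0.204,1.631
Sample 2,Flea market,Pear,2020,42.0,40.1,2.5,0.530,3.031,0.206,0.030,0.024,<LOD,0.150
Sample 3,Flea market,Mulberry and honey,2020,42.0,48.6,2.5,0.125,7.682,0.224,0.074,<LOD,0.071,0.049
Sample 4,Flea market,Apple,2020,43.0,46.4,2.5,0.040,33.524,0.170,0.004,<LOD,0.152,0.246
Sample 5,Flea market,Grape,2020,40.0,43.3,2.5,0.038,21.962,0.108,0.005,<LOD,0.181,0.180
Sample 6,Flea market,Plum,2020,38.0,42.2,2.5,0.087,25.837,2.035,0.019,<LOD,0.233,0.289
Sample 7,Flea market,Quince,2020,45.0,41.8,4.0,0.097,8.458,0.250,0.077,0.028,0.096,0.187
Sample 8,Producer's home,Grape,2017,41.0,40.3,2.5,0.170,21.978,0.156,0.020,<LOD,0.130,2.898
Sample 9,Producer's home,Grape,2022,42.0,42.2,5.0,0.035,3.989,0.073,0.009,<LOD,<LOD,0.052
Sample 10,Producer's home,Grape,2022,44.0,44.2,3.0,0.065,6.311,0.065,0.018,<LOD,<LOD,0.244
Sample 11,Producer's home,Grape,2018,42.0,42.0,4.0,0.121,9.394,0.102,0.010,<LOD,0.101,0.190
Sample 12,Producer's home,Grape,2022,43.0,44.9,5.0,0.059,8.333,0.166,0.004,4.231,0.206,0.053
Sample 13,Producer's home,Grape,2022,40.0,44.0,5.0,0.038,15.939,0.092,0.005,<LOD,0.060,0.332
Sample 14,Producer's home,Grape,2022,48.0,47.6,7.0,0.048,12.444,0.098,0.004,<LOD,0.282,0.038
Sample 15,Producer's home,Grape,2015,43.0,51.8,5.0,0.040,10.763,0.086,0.004,<LOD,0.028,0.046
Sample 16,Producer's home,Grape,2022,42.0,41.0,3.0,0.085,21.057,0.119,0.010,<LOD,0.050,0.190
Sample 17,Producer's home,Grape,2022,44.0,44.0,5.0,0.042,15.298,0.088,0.009,<LOD,0.628,0.050
Sample 18,Producer's home,,2017,,48.6,,0.112,11.480,0.178,0.012,<LOD,0.038,0.066
Sample 19,Producer's home,Plum,2021,40.0,50.3,10.0,0.097,2.663,0.049,0.004,<LOD,<LOD,0.028
Sample 20,Producer's home,,,,48.1,,0.043,6.161,0.109,0.004,<LOD,0.030,0.042
Sample 21,Producer's home,Grape,2018,43.0,47.5,3.0,0.246,19.236,0.119,0.004,<LOD,1.276,0.080
Sample 22,Producer's home,Grape,2018,42.0,45.0,3.0,0.081,20.763,0.095,0.004,<LOD,1.321,0.071
Sample 23,Producer's home,Grape,2021,44.0,48.8,3.5,0.034,36.536,0.051,0.008,<LOD,3.238,0.324
Sample 24,Producer's home,Grape,2021,42.0,47.4,4.0,0.136,6.842,0.149,0.076,<LOD,<LOD,0.346
Sample 25,Producer's home,Grape,2015,60.0,65.1,4.0,0.069,6.291,0.124,0.061,<LOD,<LOD,0.295
Sample 26,Producer's home,Grape,2018,42.0,43.4,5.0,0.038,11.570,0.965,0.005,<LOD,0.111,0.124
Sample 27,Producer's home,Plum,2013,45.0,42.6,6.0,0.560,5.158,0.218,0.028,<LOD,0.048,0.263
Sample 28,Producer's home,Pear,2015,42.0,37.9,8.0,0.139,1.033,0.318,0.021,<LOD,0.017,0.063
Sample 29,Producer's home,Grape,2015,45.0,41.1,3.0,0.089,22.942,0.162,0.015,<LOD,<LOD,0.263
Sample 30,Producer's home,Grape,2021,60.0,54.3,3.5,0.101,24.032,0.104,0.007,0.018,0.056,0.862
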