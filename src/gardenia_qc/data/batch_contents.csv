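sample_id,Geniposide,Genipin gentiobioside,Gardenoside,Shanzhiside,DAAME,SME,Geniposidic acid,Total of iridoids,Crocin I,Crocin II,Jasminoside B,Chlorogenic acid,Rutin
S1,56.157,17.254,3.324,1.616,0.279,0.240,0.288,79.159,7.733,0.879,1.184,0.175,0.452
S2,63.507,17.373,3.445,1.899,0.365,0.196,0.232,87.017,6.984,0.767,1.166,0.493,0.627
S3,47.306,8.479,3.230,0.767,0.214,0.174,0.137,60.308,7.640,1.156,0.794,0.437,1.043
S4,50.841,11.828,5.277,2.186,0.774,0.434,0.223,71.563,8.613,1.025,1.046,1.065,1.184
S5,49.480,10.326,5.043,2.159,0.821,0.452,0.246,68.526,8.122,0.905,0.956,1.386,1.315
S6,67.039,14.199,3.720,2.021,0.325,0.202,0.336,87.843,9.578,1.087,1.386,0.192,0.558
S7,57.153,20.159,3.293,1.405,0.622,0.297,0.412,83.341,6.061,1.251,1.023,0.187,0.595
S8,58.755,18.663,3.865,1.058,0.314,0.279,0.161,83.095,11.768,1.538,1.894,0.298,0.769
S9,56.628,20.945,3.687,1.737,0.277,0.183,0.244,83.701,5.586,0.909,0.947,0.275,0.536
S10,40.684,11.943,6.085,2.877,0.553,0.368,0.314,62.824,9.463,1.316,1.556,1.220,0.862
S11,49.570,12.767,3.688,1.487,0.479,0.348,0.189,68.526,8.798,1.226,1.259,0.152,0.492
S12,55.511,15.942,4.705,1.127,0.407,0.342,0.171,78.205,7.801,1.137,1.391,0.284,0.889
S13,45.203,8.848,6.438,2.488,0.802,0.256,1.499,65.534,9.038,1.578,0.949,1.900,0.478
S14,63.439,16.376,3.654,1.912,0.335,0.283,1.056,87.056,8.186,0.816,0.948,0.223,0.484
S15,57.478,14.724,2.873,1.854,0.335,0.259,0.166,77.690,10.132,1.200,1.377,0.137,0.514
S16,37.917,10.029,5.794,2.631,1.634,0.913,1.013,59.931,6.908,1.297,0.677,0.946,0.928
S17,50.662,16.733,2.693,0.936,0.565,0.404,0.132,72.124,5.735,0.777,0.562,0.566,0.491
S18,46.155,11.622,2.949,1.245,1.075,0.900,0.737,64.683,4.848,0.638,0.384,0.770,0.800
S19,46.483,9.444,5.048,2.334,0.447,0.327,0.170,64.253,9.612,1.667,1.411,0.667,0.936
S20,50.726,16.015,6.851,2.619,0.714,0.433,0.261,77.619,7.547,1.167,0.971,0.985,0.768
S21,47.560,16.348,6.315,2.257,0.872,0.551,0.250,74.153,7.438,1.055,1.086,0.734,0.665
S22,49.344,12.668,8.705,3.011,0.766,0.503,0.240,75.236,9.473,1.569,1.376,1.110,0.772
S23,61.648,15.332,3.138,1.005,0.541,0.200,0.169,82.033,11.266,1.334,1.352,0.456,0.475
S24,48.245,13.228,6.116,2.546,0.768,0.486,0.209,71.598,8.778,1.307,0.912,1.032,0.725
S25,51.362,10.919,5.128,1.502,0.527,0.368,0.256,70.062,6.948,0.952,0.790,0.476,0.742
S26,57.580,18.966,3.111,1.216,0.366,0.283,0.161,81.683,6.872,1.249,1.165,0.260,0.712
S27,50.456,13.112,3.050,1.777,0.455,0.264,0.130,69.244,10.195,1.564,1.214,0.175,0.531
S28,49.031,12.675,4.073,0.931,0.399,0.249,0.187,67.546,8.274,1.277,1.149,0.327,0.720
S29,51.922,10.231,3.632,1.167,0.469,0.348,0.277,68.045,7.475,1.024,0.920,0.618,1.007
S30,43.513,7.670,5.608,2.419,0.880,0.590,0.514,61.194,7.187,0.789,0.743,1.285,0.758
S31,54.676,9.316,4.095,1.180,0.598,0.378,0.347,70.590,6.558,1.202,1.238,0.624,1.601
S32,72.216,6.098,7.430,5.046,1.292,1.110,1.122,94.314,5.584,0.871,1.222,0.879,0.497
S33,56.122,5.352,7.029,2.854,0.739,0.561,0.474,73.131,12.837,2.978,2.015,0.584,0.334
S34,46.953,9.853,2.319,0.851,0.379,0.180,0.234,60.769,4.819,1.097,0.595,0.212,0.916
S35,56.624,15.340,0.623,1.180,5.596,1.505,0.401,81.270,6.752,1.142,0.122,0.227,0.800
S36,53.501,16.804,2.984,0.833,0.342,0.304,0.133,74.900,9.505,1.366,1.598,0.262,0.835
S37,47.872,9.927,3.013,0.885,0.564,0.353,0.141,62.754,7.241,1.305,1.148,0.379,1.002
S38,52.420,13.997,2.335,1.375,1.098,0.627,0.406,72.258,7.054,1.036,0.759,0.206,1.267
S39,50.352,13.880,5.154,0.288,0.453,0.351,0.197,70.675,6.587,0.882,1.036,1.001,0.575
S40,46.717,12.988,6.433,3.398,0.916,0.621,1.494,72.567,9.233,1.305,0.957,1.058,0.576
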