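sample_id,minor_measured_mm,minor_actual_mm,minor_error_mm,major_measured_mm,major_actual_mm,major_error_mm
1,39.329,40.866,1.537,51.136,50.774,0.362
2,40.668,41.036,0.368,57.040,56.713,0.327
3,40.770,41.939,1.169,53.405,52.856,0.549
4,40.742,41.661,0.919,54.140,53.388,0.752
5,40.617,41.828,1.211,53.291,52.478,0.813
6,42.825,42.902,0.077,54.966,54.033,0.933
7,40.445,41.302,0.857,55.053,54.321,0.732
8,41.599,42.373,0.774,54.111,53.712,0.400
9,41.746,42.147,0.401,57.377,57.132,0.245
10,42.517,43.253,0.736,56.433,56.407,0.026
11,42.046,43.360,1.314,56.237,56.376,0.139
12,40.270,41.115,0.845,55.663,55.566,0.097
13,41.385,42.198,0.813,53.052,52.312,0.740
14,41.119,42.011,0.892,54.079,54.024,0.055
15,42.264,42.862,0.598,54.105,53.613,0.492
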