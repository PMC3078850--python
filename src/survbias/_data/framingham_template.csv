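sex,age,p0
F,40,0.0
F,41,0.001615
F,42,0.003361
F,43,0.005247
F,44,0.007284
F,45,0.009482
F,46,0.011852
F,47,0.014404
F,48,0.017152
F,49,0.020107
F,50,0.023282
F,51,0.026689
F,52,0.03034
F,53,0.03425
F,54,0.038429
F,55,0.042891
F,56,0.047648
F,57,0.05271
F,58,0.058089
F,59,0.063792
F,60,0.069829
F,61,0.076205
F,62,0.082926
F,63,0.089993
F,64,0.097406
F,65,0.105163
F,66,0.113258
F,67,0.121683
F,68,0.130426
F,69,0.139472
F,70,0.148803
F,71,0.158397
F,72,0.168229
F,73,0.178273
F,74,0.188496
F,75,0.198867
F,76,0.20935
F,77,0.219909
F,78,0.230506
F,79,0.241103
F,80,0.251662
F,81,0.262145
F,82,0.272516
F,83,0.28274
F,84,0.292783
F,85,0.302616
F,86,0.31221
F,87,0.321541
F,88,0.330587
F,89,0.33933
M,40,0.0
M,41,0.002999
M,42,0.006228
M,43,0.009699
M,44,0.013429
M,45,0.017431
M,46,0.021721
M,47,0.026314
M,48,0.031225
M,49,0.036467
M,50,0.042055
M,51,0.048003
M,52,0.054321
M,53,0.061022
M,54,0.068114
M,55,0.075606
M,56,0.083501
M,57,0.091803
M,58,0.100513
M,59,0.109626
M,60,0.119136
M,61,0.129034
M,62,0.139306
M,63,0.149933
M,64,0.160896
M,65,0.172167
M,66,0.183719
M,67,0.195518
M,68,0.207529
M,69,0.219713
M,70,0.232029
M,71,0.244435
M,72,0.256884
M,73,0.269334
M,74,0.281739
M,75,0.294055
M,76,0.30624
M,77,0.318251
M,78,0.33005
M,79,0.341602
M,80,0.352873
M,81,0.363835
M,82,0.374463
M,83,0.384735
M,84,0.394633
M,85,0.404143
M,86,0.413256
M,87,0.421966
M,88,0.430268
M,89,0.438163
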