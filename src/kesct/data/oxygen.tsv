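energy_keV	mu_over_rho_cm2_g
15	1.836
15.25	1.75831
15.5	1.68509
15.75	1.61602
16	1.5508
16.25	1.48917
16.5	1.43087
16.75	1.37568
17	1.32339
17.25	1.27381
17.5	1.22675
17.75	1.18207
18	1.13961
18.25	1.09922
18.5	1.06079
18.75	1.02419
19	0.989317
19.25	0.956061
19.5	0.924331
19.75	0.894038
20	0.8651
20.25	0.843425
20.5	0.822548
20.75	0.802433
21	0.783041
21.25	0.764339
21.5	0.746295
21.75	0.728878
22	0.71206
22.25	0.695813
22.5	0.680112
22.75	0.664934
23	0.650254
23.25	0.636052
23.5	0.622307
23.75	0.609
24	0.596113
24.25	0.583627
24.5	0.571527
24.75	0.559797
25	0.548422
25.25	0.537388
25.5	0.526681
25.75	0.516289
26	0.5062
26.25	0.496401
26.5	0.486883
26.75	0.477633
27	0.468643
27.25	0.459903
27.5	0.451404
27.75	0.443136
28	0.435092
28.25	0.427263
28.5	0.419642
28.75	0.412222
29	0.404996
29.25	0.397957
29.5	0.391099
29.75	0.384415
30	0.3779
30.25	0.373783
30.5	0.369744
30.75	0.365781
31	0.361893
31.25	0.358076
31.5	0.35433
31.75	0.350652
32	0.34704
32.25	0.343493
32.5	0.34001
32.75	0.336588
33	0.333226
33.25	0.329923
33.5	0.326677
33.75	0.323487
34	0.320351
34.25	0.317268
34.5	0.314237
34.75	0.311256
35	0.308325
35.25	0.305442
35.5	0.302606
35.75	0.299816
36	0.29707
36.25	0.294369
36.5	0.291711
36.75	0.289094
37	0.286519
37.25	0.283983
37.5	0.281487
37.75	0.279029
38	0.276608
38.25	0.274224
38.5	0.271876
38.75	0.269563
39	0.267285
39.25	0.26504
39.5	0.262828
39.75	0.260648
40	0.2585
40.25	0.257113
40.5	0.255742
40.75	0.254387
41	0.253047
41.25	0.251722
41.5	0.250413
41.75	0.249117
42	0.247837
42.25	0.24657
42.5	0.245317
42.75	0.244078
43	0.242852
43.25	0.24164
43.5	0.24044
43.75	0.239253
44	0.238079
44.25	0.236917
44.5	0.235768
44.75	0.23463
45	0.233504
45.25	0.23239
45.5	0.231287
45.75	0.230195
46	0.229115
46.25	0.228045
46.5	0.226986
46.75	0.225938
47	0.2249
47.25	0.223872
47.5	0.222854
47.75	0.221846
48	0.220848
48.25	0.21986
48.5	0.218881
48.75	0.217912
49	0.216952
49.25	0.216
49.5	0.215058
49.75	0.214125
50	0.2132
50.25	0.212551
50.5	0.211906
50.75	0.211267
51	0.210633
51.25	0.210004
51.5	0.20938
51.75	0.20876
52	0.208146
52.25	0.207536
52.5	0.206931
52.75	0.20633
53	0.205735
53.25	0.205143
53.5	0.204556
53.75	0.203974
54	0.203395
54.25	0.202822
54.5	0.202252
54.75	0.201687
55	0.201125
55.25	0.200568
55.5	0.200015
55.75	0.199466
56	0.198921
56.25	0.198379
56.5	0.197842
56.75	0.197308
57	0.196778
57.25	0.196252
57.5	0.19573
57.75	0.195211
58	0.194696
58.25	0.194184
58.5	0.193676
58.75	0.193172
59	0.192671
59.25	0.192173
59.5	0.191679
59.75	0.191188
60	0.1907
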