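energy_keV	mu_over_rho_cm2_g
15	0.8071
15.25	0.779654
15.5	0.753566
15.75	0.728747
16	0.705117
16.25	0.682603
16.5	0.661134
16.75	0.640649
17	0.621088
17.25	0.602397
17.5	0.584525
17.75	0.567426
18	0.551056
18.25	0.535374
18.5	0.520343
18.75	0.505927
19	0.492094
19.25	0.478813
19.5	0.466054
19.75	0.453792
20	0.442
20.25	0.434676
20.5	0.427562
20.75	0.420647
21	0.413926
21.25	0.407389
21.5	0.401031
21.75	0.394843
22	0.38882
22.25	0.382956
22.5	0.377244
22.75	0.371679
23	0.366255
23.25	0.360968
23.5	0.355812
23.75	0.350784
24	0.345878
24.25	0.341091
24.5	0.336418
24.75	0.331855
25	0.3274
25.25	0.323047
25.5	0.318795
25.75	0.314639
26	0.310576
26.25	0.306604
26.5	0.30272
26.75	0.298921
27	0.295205
27.25	0.291568
27.5	0.288008
27.75	0.284524
28	0.281112
28.25	0.277771
28.5	0.274499
28.75	0.271293
29	0.268153
29.25	0.265074
29.5	0.262058
29.75	0.2591
30	0.2562
30.25	0.25465
30.5	0.253122
30.75	0.251616
31	0.250131
31.25	0.248666
31.5	0.247221
31.75	0.245797
32	0.244391
32.25	0.243004
32.5	0.241636
32.75	0.240286
33	0.238954
33.25	0.237639
33.5	0.236341
33.75	0.235059
34	0.233795
34.25	0.232546
34.5	0.231312
34.75	0.230094
35	0.228891
35.25	0.227703
35.5	0.22653
35.75	0.22537
36	0.224225
36.25	0.223093
36.5	0.221975
36.75	0.22087
37	0.219778
37.25	0.218698
37.5	0.217631
37.75	0.216576
38	0.215534
38.25	0.214503
38.5	0.213483
38.75	0.212476
39	0.211479
39.25	0.210493
39.5	0.209518
39.75	0.208554
40	0.2076
40.25	0.206998
40.5	0.206402
40.75	0.205811
41	0.205225
41.25	0.204645
41.5	0.204069
41.75	0.203499
42	0.202934
42.25	0.202374
42.5	0.201818
42.75	0.201267
43	0.200721
43.25	0.20018
43.5	0.199643
43.75	0.19911
44	0.198583
44.25	0.198059
44.5	0.19754
44.75	0.197025
45	0.196514
45.25	0.196007
45.5	0.195505
45.75	0.195006
46	0.194512
46.25	0.194021
46.5	0.193535
46.75	0.193052
47	0.192573
47.25	0.192097
47.5	0.191625
47.75	0.191157
48	0.190693
48.25	0.190232
48.5	0.189774
48.75	0.18932
49	0.18887
49.25	0.188422
49.5	0.187978
49.75	0.187537
50	0.1871
50.25	0.186767
50.5	0.186436
50.75	0.186107
51	0.185781
51.25	0.185457
51.5	0.185134
51.75	0.184814
52	0.184496
52.25	0.18418
52.5	0.183867
52.75	0.183555
53	0.183245
53.25	0.182937
53.5	0.182631
53.75	0.182327
54	0.182025
54.25	0.181725
54.5	0.181427
54.75	0.18113
55	0.180836
55.25	0.180543
55.5	0.180252
55.75	0.179963
56	0.179675
56.25	0.179389
56.5	0.179105
56.75	0.178823
57	0.178542
57.25	0.178263
57.5	0.177986
57.75	0.17771
58	0.177436
58.25	0.177164
58.5	0.176893
58.75	0.176624
59	0.176356
59.25	0.17609
59.5	0.175825
59.75	0.175562
60	0.1753
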