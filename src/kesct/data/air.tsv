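energy_keV	mu_over_rho_cm2_g
15	1.614
15.25	1.54771
15.5	1.48516
15.75	1.42608
16	1.37023
16.25	1.31737
16.5	1.26732
16.75	1.21988
17	1.17488
17.25	1.13216
17.5	1.09158
17.75	1.05299
18	1.01628
18.25	0.981333
18.5	0.948036
18.75	0.916294
19	0.886014
19.25	0.857112
19.5	0.829507
19.75	0.803126
20	0.7779
20.25	0.759348
20.5	0.741457
20.75	0.724197
21	0.707539
21.25	0.691454
21.5	0.675917
21.75	0.660903
22	0.646387
22.25	0.63235
22.5	0.618769
22.75	0.605625
23	0.592899
23.25	0.580574
23.5	0.568633
23.75	0.55706
24	0.54584
24.25	0.534959
24.5	0.524403
24.75	0.514159
25	0.504216
25.25	0.49456
25.5	0.485182
25.75	0.476071
26	0.467217
26.25	0.458609
26.5	0.45024
26.75	0.4421
27	0.43418
27.25	0.426474
27.5	0.418972
27.75	0.411669
28	0.404557
28.25	0.39763
28.5	0.39088
28.75	0.384303
29	0.377891
29.25	0.371641
29.5	0.365545
29.75	0.3596
30	0.3538
30.25	0.350213
30.5	0.346691
30.75	0.343232
31	0.339836
31.25	0.336501
31.5	0.333224
31.75	0.330005
32	0.326841
32.25	0.323733
32.5	0.320677
32.75	0.317674
33	0.314721
33.25	0.311817
33.5	0.308962
33.75	0.306154
34	0.303392
34.25	0.300674
34.5	0.298001
34.75	0.29537
35	0.292781
35.25	0.290234
35.5	0.287726
35.75	0.285257
36	0.282826
36.25	0.280432
36.5	0.278075
36.75	0.275754
37	0.273468
37.25	0.271216
37.5	0.268997
37.75	0.266811
38	0.264657
38.25	0.262534
38.5	0.260442
38.75	0.25838
39	0.256348
39.25	0.254344
39.5	0.252368
39.75	0.250421
40	0.2485
40.25	0.247269
40.5	0.246051
40.75	0.244847
41	0.243656
41.25	0.242478
41.5	0.241312
41.75	0.24016
42	0.239019
42.25	0.237891
42.5	0.236775
42.75	0.23567
43	0.234577
43.25	0.233495
43.5	0.232425
43.75	0.231365
44	0.230317
44.25	0.229279
44.5	0.228251
44.75	0.227234
45	0.226227
45.25	0.22523
45.5	0.224243
45.75	0.223265
46	0.222297
46.25	0.221339
46.5	0.220389
46.75	0.219449
47	0.218518
47.25	0.217596
47.5	0.216682
47.75	0.215777
48	0.214881
48.25	0.213993
48.5	0.213113
48.75	0.212241
49	0.211377
49.25	0.210521
49.5	0.209673
49.75	0.208833
50	0.208
50.25	0.20741
50.5	0.206825
50.75	0.206245
51	0.205669
51.25	0.205098
51.5	0.20453
51.75	0.203967
52	0.203409
52.25	0.202854
52.5	0.202304
52.75	0.201758
53	0.201216
53.25	0.200677
53.5	0.200143
53.75	0.199613
54	0.199087
54.25	0.198564
54.5	0.198045
54.75	0.19753
55	0.197018
55.25	0.196511
55.5	0.196006
55.75	0.195506
56	0.195008
56.25	0.194515
56.5	0.194024
56.75	0.193538
57	0.193054
57.25	0.192574
57.5	0.192097
57.75	0.191623
58	0.191153
58.25	0.190685
58.5	0.190221
58.75	0.18976
59	0.189302
59.25	0.188847
59.5	0.188395
59.75	0.187946
60	0.1875
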