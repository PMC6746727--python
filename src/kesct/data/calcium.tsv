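energy_keV	mu_over_rho_cm2_g
15	32.94
15.25	31.4181
15.5	29.9895
15.75	28.6473
16	27.3848
16.25	26.1963
16.5	25.0763
16.75	24.02
17	23.0229
17.25	22.0808
17.5	21.1901
17.75	20.3471
18	19.5488
18.25	18.7921
18.5	18.0745
18.75	17.3933
19	16.7463
19.25	16.1314
19.5	15.5466
19.75	14.99
20	14.46
20.25	13.9767
20.5	13.5153
20.75	13.0744
21	12.6529
21.25	12.2497
21.5	11.8639
21.75	11.4945
22	11.1406
22.25	10.8014
22.5	10.4761
22.75	10.1641
23	9.86468
23.25	9.57714
23.5	9.30093
23.75	9.03548
24	8.78026
24.25	8.53479
24.5	8.2986
24.75	8.07124
25	7.8523
25.25	7.64139
25.5	7.43815
25.75	7.24221
26	7.05325
26.25	6.87096
26.5	6.69504
26.75	6.52522
27	6.36123
27.25	6.20281
27.5	6.04973
27.75	5.90176
28	5.75869
28.25	5.62031
28.5	5.48644
28.75	5.35688
29	5.23146
29.25	5.11002
29.5	4.99239
29.75	4.87844
30	4.768
30.25	4.66365
30.5	4.56241
30.75	4.46417
31	4.36881
31.25	4.27623
31.5	4.18633
31.75	4.09901
32	4.01417
32.25	3.93173
32.5	3.85159
32.75	3.77369
33	3.69794
33.25	3.62426
33.5	3.55258
33.75	3.48285
34	3.41497
34.25	3.34891
34.5	3.28459
34.75	3.22195
35	3.16095
35.25	3.10152
35.5	3.04362
35.75	2.9872
36	2.9322
36.25	2.87858
36.5	2.82631
36.75	2.77533
37	2.72561
37.25	2.6771
37.5	2.62977
37.75	2.58359
38	2.53851
38.25	2.49451
38.5	2.45155
38.75	2.4096
39	2.36863
39.25	2.32862
39.5	2.28952
39.75	2.25133
40	2.214
40.25	2.17736
40.5	2.14156
40.75	2.10655
41	2.07233
41.25	2.03886
41.5	2.00614
41.75	1.97413
42	1.94282
42.25	1.91218
42.5	1.88221
42.75	1.85287
43	1.82416
43.25	1.79606
43.5	1.76855
43.75	1.74162
44	1.71524
44.25	1.68941
44.5	1.66412
44.75	1.63934
45	1.61506
45.25	1.59127
45.5	1.56797
45.75	1.54513
46	1.52274
46.25	1.5008
46.5	1.47928
46.75	1.45819
47	1.43751
47.25	1.41724
47.5	1.39735
47.75	1.37784
48	1.35871
48.25	1.33994
48.5	1.32152
48.75	1.30345
49	1.28571
49.25	1.26831
49.5	1.25123
49.75	1.23446
50	1.218
50.25	1.20353
50.5	1.18931
50.75	1.17533
51	1.16157
51.25	1.14805
51.5	1.13474
51.75	1.12165
52	1.10878
52.25	1.09611
52.5	1.08365
52.75	1.07139
53	1.05932
53.25	1.04745
53.5	1.03576
53.75	1.02426
54	1.01294
54.25	1.00179
54.5	0.990821
54.75	0.980017
55	0.969381
55.25	0.958907
55.5	0.948592
55.75	0.938435
56	0.92843
56.25	0.918577
56.5	0.90887
56.75	0.899309
57	0.88989
57.25	0.880609
57.5	0.871466
57.75	0.862456
58	0.853578
58.25	0.844829
58.5	0.836206
58.75	0.827708
59	0.819331
59.25	0.811074
59.5	0.802935
59.75	0.794911
60	0.787
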