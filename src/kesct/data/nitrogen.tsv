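energy_keV	mu_over_rho_cm2_g
15	1.24935
15.25	1.20065
15.5	1.15459
15.75	1.11099
16	1.06969
16.25	1.03053
16.5	0.993368
16.75	0.958075
17	0.924531
17.25	0.892626
17.5	0.862257
17.75	0.833331
18	0.805759
18.25	0.779461
18.5	0.754363
18.75	0.730393
19	0.707487
19.25	0.685585
19.5	0.664631
19.75	0.644572
20	0.62536
20.25	0.612121
20.5	0.59932
20.75	0.586937
21	0.574953
21.25	0.563352
21.5	0.552117
21.75	0.541231
22	0.530681
22.25	0.520452
22.5	0.510532
22.75	0.500907
23	0.491566
23.25	0.482497
23.5	0.47369
23.75	0.465134
24	0.45682
24.25	0.448739
24.5	0.440881
24.75	0.433238
25	0.425803
25.25	0.418567
25.5	0.411524
25.75	0.404666
26	0.397988
26.25	0.391482
26.5	0.385142
26.75	0.378963
27	0.372939
27.25	0.367066
27.5	0.361337
27.75	0.355748
28	0.350295
28.25	0.344972
28.5	0.339777
28.75	0.334704
29	0.329749
29.25	0.32491
29.5	0.320182
29.75	0.315561
30	0.311045
30.25	0.308414
30.5	0.305825
30.75	0.30328
31	0.300776
31.25	0.298312
31.5	0.295889
31.75	0.293503
32	0.291156
32.25	0.288845
32.5	0.28657
32.75	0.284331
33	0.282125
33.25	0.279953
33.5	0.277815
33.75	0.275708
34	0.273632
34.25	0.271587
34.5	0.269572
34.75	0.267587
35	0.26563
35.25	0.263701
35.5	0.2618
35.75	0.259926
36	0.258078
36.25	0.256255
36.5	0.254458
36.75	0.252686
37	0.250938
37.25	0.249214
37.5	0.247513
37.75	0.245835
38	0.244179
38.25	0.242545
38.5	0.240932
38.75	0.239341
39	0.23777
39.25	0.23622
39.5	0.234689
39.75	0.233178
40	0.231686
40.25	0.230743
40.5	0.229811
40.75	0.228887
41	0.227973
41.25	0.227069
41.5	0.226173
41.75	0.225286
42	0.224408
42.25	0.223538
42.5	0.222677
42.75	0.221825
43	0.22098
43.25	0.220144
43.5	0.219315
43.75	0.218495
44	0.217682
44.25	0.216877
44.5	0.216079
44.75	0.215288
45	0.214505
45.25	0.213729
45.5	0.21296
45.75	0.212198
46	0.211443
46.25	0.210695
46.5	0.209953
46.75	0.209218
47	0.208489
47.25	0.207767
47.5	0.207051
47.75	0.206341
48	0.205638
48.25	0.20494
48.5	0.204248
48.75	0.203563
49	0.202883
49.25	0.202208
49.5	0.20154
49.75	0.200877
50	0.200219
50.25	0.199739
50.5	0.199262
50.75	0.198789
51	0.198319
51.25	0.197853
51.5	0.19739
51.75	0.19693
52	0.196474
52.25	0.196021
52.5	0.195571
52.75	0.195124
53	0.19468
53.25	0.194239
53.5	0.193802
53.75	0.193367
54	0.192936
54.25	0.192507
54.5	0.192082
54.75	0.191659
55	0.191239
55.25	0.190822
55.5	0.190407
55.75	0.189996
56	0.189587
56.25	0.189181
56.5	0.188777
56.75	0.188376
57	0.187978
57.25	0.187583
57.5	0.187189
57.75	0.186799
58	0.186411
58.25	0.186025
58.5	0.185642
58.75	0.185261
59	0.184883
59.25	0.184507
59.5	0.184133
59.75	0.183762
60	0.183393
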