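energy_keV	mu_over_rho_cm2_g
15	0.975788
15.25	0.940639
15.5	0.907346
15.75	0.875786
16	0.84584
16.25	0.817403
16.5	0.790378
16.75	0.764673
17	0.740206
17.25	0.7169
17.5	0.694683
17.75	0.673491
18	0.653262
18.25	0.63394
18.5	0.615472
18.75	0.597809
19	0.580907
19.25	0.564722
19.5	0.549216
19.75	0.534352
20	0.520095
20.25	0.510526
20.5	0.501263
20.75	0.492293
21	0.483602
21.25	0.47518
21.5	0.467014
21.75	0.459093
22	0.451408
22.25	0.443949
22.5	0.436707
22.75	0.429672
23	0.422838
23.25	0.416195
23.5	0.409737
23.75	0.403456
24	0.397346
24.25	0.3914
24.5	0.385612
24.75	0.379976
25	0.374487
25.25	0.36914
25.5	0.363929
25.75	0.35885
26	0.353897
26.25	0.349068
26.5	0.344356
26.75	0.33976
27	0.335273
27.25	0.330894
27.5	0.326617
27.75	0.322441
28	0.318361
28.25	0.314375
28.5	0.31048
28.75	0.306672
29	0.30295
29.25	0.29931
29.5	0.295749
29.75	0.292266
30	0.288858
30.25	0.286902
30.5	0.284977
30.75	0.283083
31	0.281219
31.25	0.279383
31.5	0.277576
31.75	0.275797
32	0.274045
32.25	0.272319
32.5	0.270619
32.75	0.268944
33	0.267294
33.25	0.265668
33.5	0.264066
33.75	0.262487
34	0.26093
34.25	0.259395
34.5	0.257882
34.75	0.25639
35	0.254919
35.25	0.253468
35.5	0.252037
35.75	0.250625
36	0.249232
36.25	0.247858
36.5	0.246502
36.75	0.245164
37	0.243843
37.25	0.24254
37.5	0.241253
37.75	0.239983
38	0.238729
38.25	0.237491
38.5	0.236268
38.75	0.235061
39	0.233868
39.25	0.232691
39.5	0.231527
39.75	0.230378
40	0.229243
40.25	0.22851
40.5	0.227785
40.75	0.227067
41	0.226356
41.25	0.225652
41.5	0.224954
41.75	0.224263
42	0.223579
42.25	0.222901
42.5	0.22223
42.75	0.221565
43	0.220906
43.25	0.220253
43.5	0.219606
43.75	0.218965
44	0.218329
44.25	0.2177
44.5	0.217076
44.75	0.216457
45	0.215844
45.25	0.215237
45.5	0.214635
45.75	0.214038
46	0.213446
46.25	0.212859
46.5	0.212277
46.75	0.211701
47	0.211129
47.25	0.210562
47.5	0.209999
47.75	0.209442
48	0.208889
48.25	0.20834
48.5	0.207796
48.75	0.207257
49	0.206722
49.25	0.206191
49.5	0.205664
49.75	0.205142
50	0.204623
50.25	0.204232
50.5	0.203843
50.75	0.203457
51	0.203074
51.25	0.202693
51.5	0.202315
51.75	0.20194
52	0.201567
52.25	0.201197
52.5	0.200829
52.75	0.200464
53	0.200101
53.25	0.19974
53.5	0.199382
53.75	0.199027
54	0.198674
54.25	0.198323
54.5	0.197974
54.75	0.197628
55	0.197284
55.25	0.196942
55.5	0.196602
55.75	0.196264
56	0.195929
56.25	0.195596
56.5	0.195265
56.75	0.194936
57	0.194609
57.25	0.194284
57.5	0.193961
57.75	0.19364
58	0.193321
58.25	0.193004
58.5	0.192689
58.75	0.192375
59	0.192064
59.25	0.191755
59.5	0.191447
59.75	0.191141
60	0.190837
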