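energy_keV	mu_over_rho_cm2_g
15	1.673
15.25	1.60466
15.5	1.54016
15.75	1.47923
16	1.4216
16.25	1.36707
16.5	1.31541
16.75	1.26643
17	1.21997
17.25	1.17585
17.5	1.13393
17.75	1.09407
18	1.05613
18.25	1.02001
18.5	0.98559
18.75	0.95277
19	0.921456
19.25	0.891561
19.5	0.863003
19.75	0.835706
20	0.8096
20.25	0.790772
20.5	0.772605
20.75	0.755069
21	0.738133
21.25	0.721771
21.5	0.705956
21.75	0.690665
22	0.675875
22.25	0.661563
22.5	0.647708
22.75	0.634293
23	0.621297
23.25	0.608704
23.5	0.596496
23.75	0.584659
24	0.573177
24.25	0.562036
24.5	0.551222
24.75	0.540723
25	0.530527
25.25	0.520622
25.5	0.510996
25.75	0.50164
26	0.492542
26.25	0.483695
26.5	0.475088
26.75	0.466713
27	0.458561
27.25	0.450625
27.5	0.442897
27.75	0.43537
28	0.428036
28.25	0.42089
28.5	0.413924
28.75	0.407133
29	0.40051
29.25	0.394051
29.5	0.38775
29.75	0.381601
30	0.3756
30.25	0.371973
30.5	0.36841
30.75	0.364909
31	0.36147
31.25	0.358091
31.5	0.35477
31.75	0.351505
32	0.348296
32.25	0.345141
32.5	0.342038
32.75	0.338987
33	0.335985
33.25	0.333033
33.5	0.330129
33.75	0.327271
34	0.324458
34.25	0.321691
34.5	0.318966
34.75	0.316284
35	0.313644
35.25	0.311044
35.5	0.308484
35.75	0.305963
36	0.30348
36.25	0.301034
36.5	0.298624
36.75	0.29625
37	0.29391
37.25	0.291605
37.5	0.289333
37.75	0.287093
38	0.284886
38.25	0.28271
38.5	0.280564
38.75	0.278448
39	0.276362
39.25	0.274305
39.5	0.272276
39.75	0.270274
40	0.2683
40.25	0.267047
40.5	0.265808
40.75	0.264583
41	0.26337
41.25	0.26217
41.5	0.260983
41.75	0.259809
42	0.258646
42.25	0.257496
42.5	0.256357
42.75	0.255231
43	0.254115
43.25	0.253011
43.5	0.251918
43.75	0.250836
44	0.249765
44.25	0.248705
44.5	0.247654
44.75	0.246615
45	0.245585
45.25	0.244565
45.5	0.243555
45.75	0.242555
46	0.241564
46.25	0.240583
46.5	0.239611
46.75	0.238648
47	0.237694
47.25	0.236748
47.5	0.235812
47.75	0.234884
48	0.233965
48.25	0.233053
48.5	0.232151
48.75	0.231256
49	0.230369
49.25	0.22949
49.5	0.228619
49.75	0.227756
50	0.2269
50.25	0.226298
50.5	0.225701
50.75	0.225108
51	0.224519
51.25	0.223935
51.5	0.223355
51.75	0.22278
52	0.222209
52.25	0.221642
52.5	0.221079
52.75	0.22052
53	0.219966
53.25	0.219415
53.5	0.218868
53.75	0.218325
54	0.217786
54.25	0.217251
54.5	0.21672
54.75	0.216192
55	0.215668
55.25	0.215148
55.5	0.214631
55.75	0.214118
56	0.213608
56.25	0.213102
56.5	0.212599
56.75	0.212099
57	0.211603
57.25	0.211111
57.5	0.210621
57.75	0.210135
58	0.209652
58.25	0.209172
58.5	0.208696
58.75	0.208222
59	0.207752
59.25	0.207284
59.5	0.20682
59.75	0.206358
60	0.2059
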