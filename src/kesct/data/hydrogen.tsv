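energy_keV	mu_over_rho_cm2_g
15	0.3764
15.25	0.376
15.5	0.375607
15.75	0.375221
16	0.374841
16.25	0.374467
16.5	0.3741
16.75	0.373738
17	0.373382
17.25	0.373032
17.5	0.372687
17.75	0.372347
18	0.372012
18.25	0.371682
18.5	0.371357
18.75	0.371037
19	0.370721
19.25	0.370409
19.5	0.370102
19.75	0.369799
20	0.3695
20.25	0.369111
20.5	0.368726
20.75	0.368347
21	0.367973
21.25	0.367604
21.5	0.367239
21.75	0.366879
22	0.366523
22.25	0.366172
22.5	0.365824
22.75	0.365482
23	0.365143
23.25	0.364808
23.5	0.364477
23.75	0.364149
24	0.363826
24.25	0.363506
24.5	0.36319
24.75	0.362877
25	0.362568
25.25	0.362261
25.5	0.361959
25.75	0.361659
26	0.361363
26.25	0.361069
26.5	0.360779
26.75	0.360491
27	0.360207
27.25	0.359925
27.5	0.359646
27.75	0.35937
28	0.359097
28.25	0.358826
28.5	0.358558
28.75	0.358292
29	0.358029
29.25	0.357768
29.5	0.35751
29.75	0.357254
30	0.357
30.25	0.356672
30.5	0.356347
30.75	0.356025
31	0.355705
31.25	0.355389
31.5	0.355075
31.75	0.354764
32	0.354456
32.25	0.354151
32.5	0.353848
32.75	0.353548
33	0.35325
33.25	0.352955
33.5	0.352662
33.75	0.352371
34	0.352083
34.25	0.351798
34.5	0.351514
34.75	0.351233
35	0.350954
35.25	0.350678
35.5	0.350403
35.75	0.350131
36	0.349861
36.25	0.349592
36.5	0.349326
36.75	0.349062
37	0.3488
37.25	0.34854
37.5	0.348282
37.75	0.348025
38	0.347771
38.25	0.347518
38.5	0.347268
38.75	0.347019
39	0.346771
39.25	0.346526
39.5	0.346282
39.75	0.34604
40	0.3458
40.25	0.345508
40.5	0.345218
40.75	0.344931
41	0.344645
41.25	0.344361
41.5	0.344079
41.75	0.343799
42	0.343521
42.25	0.343245
42.5	0.342971
42.75	0.342698
43	0.342428
43.25	0.342159
43.5	0.341892
43.75	0.341626
44	0.341362
44.25	0.3411
44.5	0.34084
44.75	0.340582
45	0.340324
45.25	0.340069
45.5	0.339815
45.75	0.339563
46	0.339312
46.25	0.339063
46.5	0.338816
46.75	0.33857
47	0.338325
47.25	0.338082
47.5	0.33784
47.75	0.3376
48	0.337361
48.25	0.337124
48.5	0.336888
48.75	0.336653
49	0.33642
49.25	0.336188
49.5	0.335957
49.75	0.335728
50	0.3355
50.25	0.335236
50.5	0.334974
50.75	0.334714
51	0.334455
51.25	0.334197
51.5	0.333941
51.75	0.333687
52	0.333433
52.25	0.333181
52.5	0.332931
52.75	0.332682
53	0.332434
53.25	0.332188
53.5	0.331943
53.75	0.331699
54	0.331457
54.25	0.331215
54.5	0.330976
54.75	0.330737
55	0.3305
55.25	0.330264
55.5	0.330029
55.75	0.329795
56	0.329563
56.25	0.329332
56.5	0.329102
56.75	0.328873
57	0.328645
57.25	0.328419
57.5	0.328193
57.75	0.327969
58	0.327746
58.25	0.327524
58.5	0.327303
58.75	0.327083
59	0.326864
59.25	0.326647
59.5	0.32643
59.75	0.326215
60	0.326
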