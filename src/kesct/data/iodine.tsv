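energy_keV	mu_over_rho_cm2_g
15	55.12
15.25	52.7237
15.5	50.468
15.75	48.3427
16	46.3382
16.25	44.4461
16.5	42.6583
16.75	40.9677
17	39.3677
17.25	37.8522
17.5	36.4156
17.75	35.0528
18	33.759
18.25	32.5298
18.5	31.3611
18.75	30.2494
19	29.1909
19.25	28.1827
19.5	27.2216
19.75	26.3049
20	25.43
20.25	24.5958
20.5	23.7986
20.75	23.0365
21	22.3075
21.25	21.6098
21.5	20.9417
21.75	20.3016
22	19.6881
22.25	19.0997
22.5	18.5352
22.75	17.9933
23	17.473
23.25	16.9731
23.5	16.4926
23.75	16.0305
24	15.5861
24.25	15.1584
24.5	14.7466
24.75	14.3501
25	13.968
25.25	13.5997
25.5	13.2447
25.75	12.9022
26	12.5718
26.25	12.2529
26.5	11.945
26.75	11.6476
27	11.3602
27.25	11.0826
27.5	10.8141
27.75	10.5545
28	10.3034
28.25	10.0603
28.5	9.82514
28.75	9.59741
29	9.37687
29.25	9.16322
29.5	8.9562
29.75	8.75554
30	8.561
30.25	8.37398
30.5	8.19254
30.75	8.01647
31	7.84556
31.25	7.67962
31.5	7.51847
31.75	7.36194
32	7.20985
32.25	7.06206
32.5	6.9184
32.75	6.77873
33	6.64291
33.1694	6.553
33.1694	35.82
33.25	35.5965
33.5	34.9154
33.75	34.2523
34	33.6065
34.25	32.9775
34.5	32.3647
34.75	31.7676
35	31.1857
35.25	30.6185
35.5	30.0655
35.75	29.5262
36	29.0003
36.25	28.4873
36.5	27.9868
36.75	27.4984
37	27.0218
37.25	26.5565
37.5	26.1023
37.75	25.6588
38	25.2257
38.25	24.8027
38.5	24.3895
38.75	23.9857
39	23.5912
39.25	23.2056
39.5	22.8287
39.75	22.4603
40	22.1
40.25	21.7423
40.5	21.3926
40.75	21.0506
41	20.7162
41.25	20.389
41.5	20.0689
41.75	19.7557
42	19.4493
42.25	19.1493
42.5	18.8557
42.75	18.5684
43	18.287
43.25	18.0115
43.5	17.7416
43.75	17.4774
44	17.2185
44.25	16.9649
44.5	16.7165
44.75	16.473
45	16.2344
45.25	16.0006
45.5	15.7714
45.75	15.5467
46	15.3264
46.25	15.1104
46.5	14.8986
46.75	14.6909
47	14.4871
47.25	14.2872
47.5	14.0912
47.75	13.8988
48	13.71
48.25	13.5248
48.5	13.343
48.75	13.1645
49	12.9893
49.25	12.8174
49.5	12.6486
49.75	12.4828
50	12.32
50.25	12.1573
50.5	11.9976
50.75	11.8408
51	11.6867
51.25	11.5354
51.5	11.3868
51.75	11.2408
52	11.0974
52.25	10.9565
52.5	10.818
52.75	10.6819
53	10.5482
53.25	10.4167
53.5	10.2875
53.75	10.1605
54	10.0356
54.25	9.91286
54.5	9.79215
54.75	9.67346
55	9.55673
55.25	9.44193
55.5	9.32902
55.75	9.21796
56	9.1087
56.25	9.00123
56.5	8.89548
56.75	8.79144
57	8.68907
57.25	8.58832
57.5	8.48918
57.75	8.3916
58	8.29556
58.25	8.20103
58.5	8.10797
58.75	8.01635
59	7.92616
59.25	7.83735
59.5	7.74991
59.75	7.6638
60	7.579
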