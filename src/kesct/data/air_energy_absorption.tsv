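energy_keV	mu_over_rho_cm2_g
15	1.334
15.25	1.2663
15.5	1.20306
15.75	1.14392
16	1.08854
16.25	1.03664
16.5	0.987959
16.75	0.942241
17	0.899269
17.25	0.858843
17.5	0.820776
17.75	0.784902
18	0.751065
18.25	0.719123
18.5	0.688948
18.75	0.660418
19	0.633425
19.25	0.607866
19.5	0.583649
19.75	0.560687
20	0.5389
20.25	0.51858
20.5	0.499261
20.75	0.480884
21	0.463391
21.25	0.44673
21.5	0.430853
21.75	0.415714
22	0.401271
22.25	0.387484
22.5	0.374317
22.75	0.361736
23	0.349709
23.25	0.338205
23.5	0.327196
23.75	0.316656
24	0.306562
24.25	0.296888
24.5	0.287615
24.75	0.278721
25	0.270187
25.25	0.261995
25.5	0.254129
25.75	0.246573
26	0.239311
26.25	0.232329
26.5	0.225614
26.75	0.219154
27	0.212936
27.25	0.20695
27.5	0.201184
27.75	0.195629
28	0.190275
28.25	0.185113
28.5	0.180135
28.75	0.175332
29	0.170698
29.25	0.166224
29.5	0.161904
29.75	0.157732
30	0.1537
30.25	0.150147
30.5	0.146705
30.75	0.143369
31	0.140135
31.25	0.136999
31.5	0.133957
31.75	0.131006
32	0.128142
32.25	0.125363
32.5	0.122664
32.75	0.120044
33	0.117499
33.25	0.115027
33.5	0.112624
33.75	0.110289
34	0.108019
34.25	0.105812
34.5	0.103666
34.75	0.101578
35	0.0995465
35.25	0.0975698
35.5	0.095646
35.75	0.0937732
36	0.0919498
36.25	0.090174
36.5	0.0884444
36.75	0.0867595
37	0.0851177
37.25	0.0835178
37.5	0.0819583
37.75	0.080438
38	0.0789557
38.25	0.0775102
38.5	0.0761003
38.75	0.0747249
39	0.0733829
39.25	0.0720735
39.5	0.0707954
39.75	0.0695479
40	0.06833
40.25	0.0673615
40.5	0.0664126
40.75	0.0654828
41	0.0645715
41.25	0.0636784
41.5	0.0628029
41.75	0.0619446
42	0.061103
42.25	0.0602778
42.5	0.0594685
42.75	0.0586747
43	0.057896
43.25	0.0571321
43.5	0.0563826
43.75	0.0556471
44	0.0549253
44.25	0.054217
44.5	0.0535216
44.75	0.052839
45	0.0521688
45.25	0.0515108
45.5	0.0508646
45.75	0.0502301
46	0.0496068
46.25	0.0489945
46.5	0.0483931
46.75	0.0478022
47	0.0472217
47.25	0.0466512
47.5	0.0460905
47.75	0.0455395
48	0.0449979
48.25	0.0444655
48.5	0.0439421
48.75	0.0434275
49	0.0429215
49.25	0.0424239
49.5	0.0419346
49.75	0.0414534
50	0.04098
50.25	0.0406469
50.5	0.0403182
50.75	0.0399938
51	0.0396735
51.25	0.0393573
51.5	0.0390452
51.75	0.0387371
52	0.0384328
52.25	0.0381324
52.5	0.0378357
52.75	0.0375428
53	0.0372535
53.25	0.0369677
53.5	0.0366855
53.75	0.0364067
54	0.0361314
54.25	0.0358593
54.5	0.0355906
54.75	0.0353251
55	0.0350627
55.25	0.0348035
55.5	0.0345474
55.75	0.0342942
56	0.0340441
56.25	0.0337969
56.5	0.0335526
56.75	0.033311
57	0.0330723
57.25	0.0328364
57.5	0.0326031
57.75	0.0323725
58	0.0321445
58.25	0.0319191
58.5	0.0316962
58.75	0.0314758
59	0.0312579
59.25	0.0310424
59.5	0.0308292
59.75	0.0306185
60	0.03041
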