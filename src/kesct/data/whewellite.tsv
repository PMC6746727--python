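energy_keV	mu_over_rho_cm2_g
15	10.1785
15.25	9.71396
15.5	9.27773
15.75	8.86765
16	8.48176
16.25	8.1183
16.5	7.77565
16.75	7.45232
17	7.14696
17.25	6.85833
17.5	6.58528
17.75	6.32678
18	6.08185
18.25	5.84961
18.5	5.62925
18.75	5.41999
19	5.22116
19.25	5.03209
19.5	4.8522
19.75	4.68093
20	4.51776
20.25	4.37213
20.5	4.23294
20.75	4.09984
21	3.9725
21.25	3.85059
21.5	3.73383
21.75	3.62194
22	3.51467
22.25	3.41177
22.5	3.31302
22.75	3.2182
23	3.12713
23.25	3.03961
23.5	2.95547
23.75	2.87454
24	2.79667
24.25	2.72171
24.5	2.64952
24.75	2.57998
25	2.51296
25.25	2.44835
25.5	2.38603
25.75	2.32591
26	2.26788
26.25	2.21186
26.5	2.15775
26.75	2.10548
27	2.05496
27.25	2.00612
27.5	1.95888
27.75	1.91319
28	1.86898
28.25	1.82619
28.5	1.78475
28.75	1.74462
29	1.70574
29.25	1.66807
29.5	1.63155
29.75	1.59614
30	1.5618
30.25	1.53066
30.5	1.50043
30.75	1.47106
31	1.44252
31.25	1.41479
31.5	1.38784
31.75	1.36164
32	1.33615
32.25	1.31137
32.5	1.28725
32.75	1.26378
33	1.24094
33.25	1.2187
33.5	1.19704
33.75	1.17595
34	1.15541
34.25	1.13539
34.5	1.11588
34.75	1.09686
35	1.07832
35.25	1.06025
35.5	1.04261
35.75	1.02541
36	1.00863
36.25	0.992259
36.5	0.976277
36.75	0.960675
37	0.945443
37.25	0.930568
37.5	0.916041
37.75	0.90185
38	0.887985
38.25	0.874438
38.5	0.861197
38.75	0.848255
39	0.835603
39.25	0.823231
39.5	0.811134
39.75	0.799301
40	0.787726
40.25	0.776815
40.5	0.76614
40.75	0.755696
41	0.745474
41.25	0.73547
41.5	0.725678
41.75	0.716091
42	0.706704
42.25	0.697512
42.5	0.688509
42.75	0.67969
43	0.671051
43.25	0.662586
43.5	0.654291
43.75	0.646162
44	0.638194
44.25	0.630384
44.5	0.622726
44.75	0.615218
45	0.607855
45.25	0.600633
45.5	0.59355
45.75	0.586602
46	0.579785
46.25	0.573096
46.5	0.566533
46.75	0.560091
47	0.553768
47.25	0.547562
47.5	0.541468
47.75	0.535486
48	0.529611
48.25	0.523842
48.5	0.518176
48.75	0.51261
49	0.507143
49.25	0.501771
49.5	0.496494
49.75	0.491308
50	0.486211
50.25	0.48183
50.5	0.477517
50.75	0.473274
51	0.469097
51.25	0.464985
51.5	0.460937
51.75	0.456952
52	0.453029
52.25	0.449165
52.5	0.445361
52.75	0.441614
53	0.437923
53.25	0.434289
53.5	0.430708
53.75	0.427181
54	0.423705
54.25	0.420281
54.5	0.416907
54.75	0.413582
55	0.410306
55.25	0.407076
55.5	0.403893
55.75	0.400755
56	0.397662
56.25	0.394613
56.5	0.391606
56.75	0.388642
57	0.385719
57.25	0.382836
57.5	0.379994
57.75	0.37719
58	0.374424
58.25	0.371697
58.5	0.369006
58.75	0.366351
59	0.363732
59.25	0.361148
59.5	0.358598
59.75	0.356082
60	0.353599
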