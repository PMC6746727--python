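energy_keV	mu_over_rho_cm2_g
15	9.24485
15.25	8.82374
15.5	8.42825
15.75	8.05645
16	7.70655
16.25	7.37698
16.5	7.06625
16.75	6.77302
17	6.49608
17.25	6.23429
17.5	5.98662
17.75	5.75213
18	5.52995
18.25	5.31926
18.5	5.11933
18.75	4.92947
19	4.74906
19.25	4.5775
19.5	4.41426
19.75	4.25883
20	4.11074
20.25	3.97898
20.5	3.85303
20.75	3.73258
21	3.61732
21.25	3.50696
21.5	3.40125
21.75	3.29994
22	3.2028
22.25	3.10961
22.5	3.02016
22.75	2.93427
23	2.85176
23.25	2.77246
23.5	2.6962
23.75	2.62286
24	2.55227
24.25	2.48432
24.5	2.41887
24.75	2.35582
25	2.29504
25.25	2.23644
25.5	2.17992
25.75	2.12538
26	2.07274
26.25	2.0219
26.5	1.9728
26.75	1.92536
27	1.87951
27.25	1.83517
27.5	1.79229
27.75	1.75081
28	1.71066
28.25	1.67179
28.5	1.63416
28.75	1.59771
29	1.56239
29.25	1.52816
29.5	1.49498
29.75	1.4628
30	1.43159
30.25	1.40347
30.5	1.37615
30.75	1.34962
31	1.32383
31.25	1.29877
31.5	1.27441
31.75	1.25072
32	1.22768
32.25	1.20526
32.5	1.18345
32.75	1.16222
33	1.14155
33.25	1.12143
33.5	1.10183
33.75	1.08274
34	1.06414
34.25	1.04601
34.5	1.02835
34.75	1.01112
35	0.99433
35.25	0.977951
35.5	0.961975
35.75	0.946388
36	0.931179
36.25	0.916334
36.5	0.901844
36.75	0.887697
37	0.873882
37.25	0.86039
37.5	0.847211
37.75	0.834335
38	0.821753
38.25	0.809456
38.5	0.797437
38.75	0.785687
39	0.774199
39.25	0.762963
39.5	0.751975
39.75	0.741226
40	0.730709
40.25	0.720857
40.5	0.711216
40.75	0.701782
41	0.692549
41.25	0.683511
41.5	0.674662
41.75	0.665998
42	0.657513
42.25	0.649202
42.5	0.641062
42.75	0.633087
43	0.625273
43.25	0.617616
43.5	0.610112
43.75	0.602756
44	0.595545
44.25	0.588475
44.5	0.581543
44.75	0.574745
45	0.568077
45.25	0.561537
45.5	0.55512
45.75	0.548825
46	0.542648
46.25	0.536586
46.5	0.530637
46.75	0.524797
47	0.519064
47.25	0.513435
47.5	0.507909
47.75	0.502481
48	0.497151
48.25	0.491916
48.5	0.486774
48.75	0.481722
49	0.476758
49.25	0.47188
49.5	0.467087
49.75	0.462377
50	0.457747
50.25	0.45378
50.5	0.449875
50.75	0.446031
51	0.442248
51.25	0.438523
51.5	0.434855
51.75	0.431244
52	0.427688
52.25	0.424187
52.5	0.420737
52.75	0.41734
53	0.413994
53.25	0.410697
53.5	0.40745
53.75	0.40425
54	0.401096
54.25	0.397989
54.5	0.394927
54.75	0.391909
55	0.388934
55.25	0.386002
55.5	0.383112
55.75	0.380262
56	0.377452
56.25	0.374682
56.5	0.371951
56.75	0.369257
57	0.3666
57.25	0.36398
57.5	0.361395
57.75	0.358846
58	0.356331
58.25	0.35385
58.5	0.351402
58.75	0.348987
59	0.346604
59.25	0.344252
59.5	0.341932
59.75	0.339641
60	0.337381
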