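energy_keV	mu_over_rho_cm2_g
15	104.85
15.25	100.201
15.5	95.828
15.75	91.7117
16	87.8329
16.25	84.1745
16.5	80.7209
16.75	77.4577
17	74.372
17.25	71.4516
17.5	68.6854
17.75	66.0633
18	63.5759
18.25	61.2146
18.5	58.9713
18.75	56.8387
19	54.81
19.25	52.8788
19.5	51.0392
19.75	49.2859
20	47.6137
20.25	46.0233
20.5	44.5046
20.75	43.0535
21	41.6663
21.25	40.3393
21.5	39.0695
21.75	37.8536
22	36.6888
22.25	35.5724
22.5	34.5018
22.75	33.4748
23	32.4891
23.25	31.5426
23.5	30.6334
23.75	29.7596
24	28.9195
24.25	28.1114
24.5	27.3338
24.75	26.5854
25	25.8646
25.25	25.1703
25.5	24.5012
25.75	23.8561
26	23.234
26.25	22.6339
26.5	22.0547
26.75	21.4955
27	20.9556
27.25	20.434
27.5	19.93
27.75	19.4428
28	18.9717
28.25	18.5161
28.5	18.0753
28.75	17.6487
29	17.2357
29.25	16.8358
29.5	16.4485
29.75	16.0732
30	15.7096
30.25	15.3598
30.5	15.0206
30.75	14.6915
31	14.3723
31.25	14.0624
31.5	13.7616
31.75	13.4696
32	13.186
32.25	12.9105
32.5	12.6428
32.75	12.3826
33	12.1297
33.25	11.8839
33.5	11.6448
33.75	11.4122
34	11.1859
34.25	10.9658
34.5	10.7515
34.75	10.5429
35	10.3398
35.25	10.1421
35.5	9.94944
35.75	9.76178
36	9.57893
36.25	9.40074
36.5	9.22705
36.75	9.05773
37	8.89263
37.25	8.73162
37.5	8.57457
37.75	8.42137
38	8.27188
38.25	8.12601
38.5	7.98363
38.75	7.84464
39	7.70895
39.25	7.57644
39.5	7.44704
39.75	7.32063
40	7.19715
40.25	7.07797
40.5	6.96148
40.75	6.8476
41	6.73627
41.25	6.62741
41.5	6.52094
41.75	6.41682
42	6.31496
42.25	6.21531
42.5	6.11781
42.75	6.02239
43	5.92901
43.25	5.8376
43.5	5.74812
43.75	5.66051
44	5.57472
44.25	5.49071
44.5	5.40843
44.75	5.32783
45	5.24887
45.25	5.17151
45.5	5.0957
45.75	5.02141
46	4.94861
46.25	4.87724
46.5	4.80728
46.75	4.73869
47	4.67144
47.25	4.60549
47.5	4.54081
47.75	4.47737
48	4.41515
48.25	4.3541
48.5	4.29421
48.75	4.23544
49	4.17777
49.25	4.12118
49.5	4.06563
49.75	4.01111
50	3.95758
50.2396	3.9072
50.2396	18.2319
50.25	18.222
50.5	17.9861
50.75	17.7543
51	17.5266
51.25	17.303
51.5	17.0832
51.75	16.8673
52	16.6552
52.25	16.4467
52.5	16.2418
52.75	16.0404
53	15.8424
53.25	15.6478
53.5	15.4565
53.75	15.2684
54	15.0835
54.25	14.9016
54.5	14.7227
54.75	14.5468
55	14.3738
55.25	14.2036
55.5	14.0362
55.75	13.8715
56	13.7094
56.25	13.55
56.5	13.3931
56.75	13.2387
57	13.0867
57.25	12.9372
57.5	12.7899
57.75	12.645
58	12.5024
58.25	12.362
58.5	12.2237
58.75	12.0875
59	11.9535
59.25	11.8215
59.5	11.6915
59.75	11.5634
60	11.4373
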