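energy_mev_u,let_kev_um
1,1004.21
1.0292,996.658
1.05925,988.934
1.09018,981.039
1.12202,972.98
1.15478,964.761
1.1885,956.389
1.22321,947.869
1.25893,939.207
1.29569,930.409
1.33352,921.481
1.37246,912.429
1.41254,903.259
1.45378,893.977
1.49624,884.589
1.53993,875.101
1.58489,865.52
1.63117,855.85
1.6788,846.099
1.72783,836.272
1.77828,826.375
1.83021,816.414
1.88365,806.395
1.93865,796.325
1.99526,786.208
2.05353,776.052
2.11349,765.861
2.1752,755.641
2.23872,745.398
2.30409,735.138
2.37137,724.865
2.44062,714.587
2.51189,704.307
2.58523,694.032
2.66073,683.765
2.73842,673.514
2.81838,663.282
2.90068,653.074
2.98538,642.896
3.07256,632.751
3.16228,622.645
3.25462,612.581
3.34965,602.565
3.44747,592.601
3.54813,582.691
3.65174,572.842
3.75837,563.055
3.86812,553.335
3.98107,543.686
4.09732,534.111
4.21697,524.613
4.3401,515.196
4.46684,505.861
4.59727,496.613
4.73151,487.454
4.86968,478.386
5.01187,469.412
5.15822,460.534
5.30884,451.755
5.46387,443.076
5.62341,434.499
5.78762,426.027
5.95662,417.659
6.13056,409.399
6.30957,401.248
6.49382,393.206
6.68344,385.274
6.8786,377.454
7.07946,369.747
7.28618,362.153
7.49894,354.673
7.71792,347.306
7.94328,340.055
8.17523,332.918
8.41395,325.896
8.65964,318.99
8.91251,312.198
9.17276,305.521
9.44061,298.959
9.71628,292.511
10,286.176
10.292,279.955
10.5925,273.847
10.9018,267.851
11.2202,261.966
11.5478,256.192
11.885,250.527
12.2321,244.971
12.5893,239.523
12.9569,234.181
13.3352,228.946
13.7246,223.814
14.1254,218.786
14.5378,213.861
14.9624,209.036
15.3993,204.311
15.8489,199.684
16.3117,195.154
16.788,190.72
17.2783,186.38
17.7828,182.133
18.3021,177.977
18.8365,173.911
19.3865,169.934
19.9526,166.044
20.5353,162.24
21.1349,158.519
21.752,154.882
22.3872,151.326
23.0409,147.85
23.7137,144.452
24.4062,141.131
25.1189,137.885
25.8523,134.714
26.6073,131.615
27.3842,128.588
28.1838,125.63
29.0068,122.741
29.8538,119.919
30.7256,117.162
31.6228,114.47
32.5462,111.841
33.4965,109.273
34.4747,106.766
35.4813,104.318
36.5174,101.928
37.5837,99.595
38.6812,97.317
39.8107,95.0933
40.9732,92.9226
42.1697,90.8038
43.401,88.7357
44.6684,86.7173
45.9727,84.7473
47.3151,82.8248
48.6968,80.9487
50.1187,79.1179
51.5822,77.3314
53.0884,75.5882
54.6387,73.8874
56.2341,72.228
57.8762,70.6089
59.5662,69.0294
61.3056,67.4885
63.0957,65.9853
64.9382,64.5189
66.8344,63.0886
68.786,61.6934
70.7946,60.3327
72.8618,59.0054
74.9894,57.711
77.1792,56.4486
79.4328,55.2175
81.7523,54.017
84.1395,52.8463
86.5964,51.7047
89.1251,50.5917
91.7276,49.5064
94.4061,48.4483
97.1628,47.4168
100,46.4111
102.92,45.4308
105.925,44.4752
109.018,43.5437
112.202,42.6357
115.478,41.7508
118.85,40.8884
122.321,40.0479
125.893,39.2288
129.569,38.4306
133.352,37.6529
137.246,36.8952
141.254,36.1569
145.378,35.4377
149.624,34.737
153.993,34.0545
158.489,33.3897
163.117,32.7422
167.88,32.1117
172.783,31.4976
177.828,30.8996
183.021,30.3174
188.365,29.7505
193.865,29.1986
199.526,28.6614
205.353,28.1385
211.349,27.6296
217.52,27.1343
223.872,26.6524
230.409,26.1834
237.137,25.7272
244.062,25.2834
251.189,24.8517
258.523,24.4319
266.073,24.0237
273.842,23.6267
281.838,23.2408
290.068,22.8657
298.538,22.5011
307.256,22.1467
316.228,21.8025
325.462,21.468
334.965,21.1432
344.747,20.8277
354.813,20.5214
365.174,20.224
375.837,19.9354
386.812,19.6553
398.107,19.3835
409.732,19.1199
421.697,18.8643
434.01,18.6165
446.684,18.3762
459.727,18.1435
473.151,17.9179
486.968,17.6995
501.187,17.488
515.822,17.2834
530.884,17.0853
546.387,16.8938
562.341,16.7085
578.762,16.5295
595.662,16.3565
613.056,16.1895
630.957,16.0283
649.382,15.8727
668.344,15.7226
687.86,15.578
707.946,15.4386
728.618,15.3044
749.894,15.1753
771.792,15.0511
794.328,14.9318
817.523,14.8172
841.395,14.7072
865.964,14.6017
891.251,14.5007
917.276,14.404
944.061,14.3115
971.628,14.2231
1000,14.1387
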