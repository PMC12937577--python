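age,sex,expectancy
0,unisex,84.5
1,unisex,83.536
2,unisex,82.571
3,unisex,81.606
4,unisex,80.641
5,unisex,79.676
6,unisex,78.71
7,unisex,77.744
8,unisex,76.779
9,unisex,75.813
10,unisex,74.847
11,unisex,73.881
12,unisex,72.915
13,unisex,71.949
14,unisex,70.983
15,unisex,70.016
16,unisex,69.05
17,unisex,68.085
18,unisex,67.119
19,unisex,66.153
20,unisex,65.188
21,unisex,64.223
22,unisex,63.258
23,unisex,62.294
24,unisex,61.33
25,unisex,60.366
26,unisex,59.403
27,unisex,58.441
28,unisex,57.479
29,unisex,56.518
30,unisex,55.558
31,unisex,54.599
32,unisex,53.641
33,unisex,52.684
34,unisex,51.729
35,unisex,50.774
36,unisex,49.821
37,unisex,48.87
38,unisex,47.921
39,unisex,46.973
40,unisex,46.028
41,unisex,45.084
42,unisex,44.143
43,unisex,43.205
44,unisex,42.269
45,unisex,41.336
46,unisex,40.407
47,unisex,39.481
48,unisex,38.558
49,unisex,37.639
50,unisex,36.725
51,unisex,35.814
52,unisex,34.909
53,unisex,34.008
54,unisex,33.113
55,unisex,32.223
56,unisex,31.339
57,unisex,30.461
58,unisex,29.59
59,unisex,28.726
60,unisex,27.87
61,unisex,27.021
62,unisex,26.18
63,unisex,25.348
64,unisex,24.524
65,unisex,23.71
66,unisex,22.906
67,unisex,22.112
68,unisex,21.329
69,unisex,20.557
70,unisex,19.796
71,unisex,19.048
72,unisex,18.312
73,unisex,17.588
74,unisex,16.879
75,unisex,16.183
76,unisex,15.501
77,unisex,14.833
78,unisex,14.181
79,unisex,13.544
80,unisex,12.922
81,unisex,12.317
82,unisex,11.728
83,unisex,11.155
84,unisex,10.599
85,unisex,10.06
86,unisex,9.538
87,unisex,9.033
88,unisex,8.546
89,unisex,8.076
90,unisex,7.624
91,unisex,7.189
92,unisex,6.772
93,unisex,6.371
94,unisex,5.988
95,unisex,5.622
96,unisex,5.272
97,unisex,4.939
98,unisex,4.622
99,unisex,4.321
100,unisex,4.035
101,unisex,3.765
102,unisex,3.509
103,unisex,3.267
104,unisex,3.039
105,unisex,2.824
0,female,86.3
1,female,85.336
2,female,84.372
3,female,83.407
4,female,82.443
5,female,81.478
6,female,80.512
7,female,79.547
8,female,78.582
9,female,77.616
10,female,76.65
11,female,75.684
12,female,74.718
13,female,73.752
14,female,72.786
15,female,71.82
16,female,70.854
17,female,69.888
18,female,68.922
19,female,67.956
20,female,66.99
21,female,66.025
22,female,65.06
23,female,64.094
24,female,63.13
25,female,62.165
26,female,61.201
27,female,60.238
28,female,59.275
29,female,58.313
30,female,57.351
31,female,56.391
32,female,55.431
33,female,54.472
34,female,53.514
35,female,52.557
36,female,51.602
37,female,50.647
38,female,49.695
39,female,48.744
40,female,47.795
41,female,46.847
42,female,45.902
43,female,44.959
44,female,44.018
45,female,43.08
46,female,42.145
47,female,41.213
48,female,40.283
49,female,39.358
50,female,38.436
51,female,37.517
52,female,36.603
53,female,35.694
54,female,34.789
55,female,33.889
56,female,32.994
57,female,32.105
58,female,31.222
59,female,30.345
60,female,29.475
61,female,28.612
62,female,27.756
63,female,26.908
64,female,26.069
65,female,25.237
66,female,24.415
67,female,23.603
68,female,22.8
69,female,22.007
70,female,21.225
71,female,20.455
72,female,19.696
73,female,18.949
74,female,18.215
75,female,17.493
76,female,16.785
77,female,16.091
78,female,15.411
79,female,14.746
80,female,14.095
81,female,13.46
82,female,12.841
83,female,12.237
84,female,11.65
85,female,11.08
86,female,10.526
87,female,9.989
88,female,9.47
89,female,8.968
90,female,8.483
91,female,8.015
92,female,7.565
93,female,7.133
94,female,6.717
95,female,6.319
96,female,5.938
97,female,5.574
98,female,5.227
99,female,4.896
100,female,4.581
101,female,4.282
102,female,3.998
103,female,3.729
104,female,3.475
105,female,3.235
0,male,82.7
1,male,81.735
2,male,80.77
3,male,79.805
4,male,78.839
5,male,77.874
6,male,76.908
7,male,75.942
8,male,74.976
9,male,74.01
10,male,73.044
11,male,72.078
12,male,71.112
13,male,70.146
14,male,69.18
15,male,68.214
16,male,67.248
17,male,66.282
18,male,65.317
19,male,64.352
20,male,63.387
21,male,62.423
22,male,61.459
23,male,60.495
24,male,59.532
25,male,58.57
26,male,57.608
27,male,56.647
28,male,55.687
29,male,54.728
30,male,53.769
31,male,52.812
32,male,51.856
33,male,50.902
34,male,49.949
35,male,48.997
36,male,48.048
37,male,47.1
38,male,46.154
39,male,45.21
40,male,44.269
41,male,43.33
42,male,42.394
43,male,41.461
44,male,40.531
45,male,39.604
46,male,38.681
47,male,37.762
48,male,36.847
49,male,35.936
50,male,35.03
51,male,34.128
52,male,33.232
53,male,32.342
54,male,31.457
55,male,30.579
56,male,29.707
57,male,28.842
58,male,27.984
59,male,27.134
60,male,26.292
61,male,25.458
62,male,24.634
63,male,23.819
64,male,23.013
65,male,22.218
66,male,21.433
67,male,20.659
68,male,19.897
69,male,19.147
70,male,18.409
71,male,17.685
72,male,16.973
73,male,16.275
74,male,15.591
75,male,14.922
76,male,14.267
77,male,13.628
78,male,13.005
79,male,12.397
80,male,11.805
81,male,11.231
82,male,10.672
83,male,10.131
84,male,9.607
85,male,9.1
86,male,8.61
87,male,8.138
88,male,7.684
89,male,7.246
90,male,6.826
91,male,6.424
92,male,6.038
93,male,5.67
94,male,5.318
95,male,4.983
96,male,4.664
97,male,4.36
98,male,4.073
99,male,3.8
100,male,3.542
101,male,3.299
102,male,3.069
103,male,2.852
104,male,2.649
105,male,2.458
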