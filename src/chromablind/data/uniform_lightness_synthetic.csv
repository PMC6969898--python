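L_star,L_uniform
0.00000,0.00000
0.50000,0.38165
1.00000,0.76495
1.50000,1.14993
2.00000,1.53658
2.50000,1.92494
3.00000,2.31502
3.50000,2.70682
4.00000,3.10037
4.50000,3.49568
5.00000,3.89278
5.50000,4.29166
6.00000,4.69236
6.50000,5.09488
7.00000,5.49925
7.50000,5.90547
8.00000,6.31358
8.50000,6.72359
9.00000,7.13550
9.50000,7.54936
10.00000,7.96516
10.50000,8.38293
11.00000,8.80270
11.50000,9.22447
12.00000,9.64827
12.50000,10.07411
13.00000,10.50203
13.50000,10.93203
14.00000,11.36415
14.50000,11.79839
15.00000,12.23479
15.50000,12.67337
16.00000,13.11414
16.50000,13.55713
17.00000,14.00236
17.50000,14.44985
18.00000,14.89964
18.50000,15.35174
19.00000,15.80618
19.50000,16.26298
20.00000,16.72218
20.50000,17.18378
21.00000,17.64783
21.50000,18.11434
22.00000,18.58336
22.50000,19.05489
23.00000,19.52897
23.50000,20.00564
24.00000,20.48492
24.50000,20.96683
25.00000,21.45142
25.50000,21.93870
26.00000,22.42872
26.50000,22.92151
27.00000,23.41710
27.50000,23.91551
28.00000,24.41680
28.50000,24.92099
29.00000,25.42812
29.50000,25.93822
30.00000,26.45134
30.50000,26.96751
31.00000,27.48677
31.50000,28.00917
32.00000,28.53474
32.50000,29.06352
33.00000,29.59557
33.50000,30.13093
34.00000,30.66963
34.50000,31.21174
35.00000,31.75730
35.50000,32.30636
36.00000,32.85897
36.50000,33.41518
37.00000,33.97506
37.50000,34.53866
38.00000,35.10604
38.50000,35.67725
39.00000,36.25238
39.50000,36.83147
40.00000,37.41461
40.50000,38.00185
41.00000,38.59329
41.50000,39.18898
42.00000,39.78901
42.50000,40.39346
43.00000,41.00241
43.50000,41.61594
44.00000,42.23411
44.50000,42.85702
45.00000,43.48470
45.50000,44.11719
46.00000,44.75451
46.50000,45.39661
47.00000,46.04337
47.50000,46.69459
48.00000,47.34994
48.50000,48.00892
49.00000,48.67085
49.50000,49.33488
50.00000,50.00000
50.50000,50.66512
51.00000,51.32915
51.50000,51.99108
52.00000,52.65006
52.50000,53.30541
53.00000,53.95663
53.50000,54.60339
54.00000,55.24549
54.50000,55.88281
55.00000,56.51530
55.50000,57.14298
56.00000,57.76589
56.50000,58.38406
57.00000,58.99759
57.50000,59.60654
58.00000,60.21099
58.50000,60.81102
59.00000,61.40671
59.50000,61.99815
60.00000,62.58539
60.50000,63.16853
61.00000,63.74762
61.50000,64.32275
62.00000,64.89396
62.50000,65.46134
63.00000,66.02494
63.50000,66.58482
64.00000,67.14103
64.50000,67.69364
65.00000,68.24270
65.50000,68.78826
66.00000,69.33037
66.50000,69.86907
67.00000,70.40443
67.50000,70.93648
68.00000,71.46526
68.50000,71.99083
69.00000,72.51323
69.50000,73.03249
70.00000,73.54866
70.50000,74.06178
71.00000,74.57188
71.50000,75.07901
72.00000,75.58320
72.50000,76.08449
73.00000,76.58290
73.50000,77.07849
74.00000,77.57128
74.50000,78.06130
75.00000,78.54858
75.50000,79.03317
76.00000,79.51508
76.50000,79.99436
77.00000,80.47103
77.50000,80.94511
78.00000,81.41664
78.50000,81.88566
79.00000,82.35217
79.50000,82.81622
80.00000,83.27782
80.50000,83.73702
81.00000,84.19382
81.50000,84.64826
82.00000,85.10036
82.50000,85.55015
83.00000,85.99764
83.50000,86.44287
84.00000,86.88586
84.50000,87.32663
85.00000,87.76521
85.50000,88.20161
86.00000,88.63585
86.50000,89.06797
87.00000,89.49797
87.50000,89.92589
88.00000,90.35173
88.50000,90.77553
89.00000,91.19730
89.50000,91.61707
90.00000,92.03484
90.50000,92.45064
91.00000,92.86450
91.50000,93.27641
92.00000,93.68642
92.50000,94.09453
93.00000,94.50075
93.50000,94.90512
94.00000,95.30764
94.50000,95.70834
95.00000,96.10722
95.50000,96.50432
96.00000,96.89963
96.50000,97.29318
97.00000,97.68498
97.50000,98.07506
98.00000,98.46342
98.50000,98.85007
99.00000,99.23505
99.50000,99.61835
100.00000,100.00000
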