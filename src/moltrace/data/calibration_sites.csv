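site_id,lat,lon,n,f_mean,f_sd,p_mean,p_sd
1,30.20,-91.70,8,-53,6.9,-24,11.3
2,30.40,-91.00,6,-44,12.1,-23,11.3
3,32.88,-88.43,4,-62,11.3,-31,11.2
4,36.78,-90.03,5,-69,9.6,-43,11.3
5,38.93,-90.58,5,-61,8.4,-45,10.9
6,39.02,-96.82,4,-63,13.1,-48,10.8
7,40.78,-91.38,4,-54,7.4,-48,10.6
8,43.28,-91.98,8,-77,5.0,-60,10.5
9,43.43,-93.22,4,-71,10.2,-59,10.2
10,46.75,-97.50,10,-100,11.4,-72,9.9
11,51.70,-106.50,6,-135,13.6,-101,8.9
12,47.70,-96.19,11,-101,13.3,-73,9.7
13,47.56,-96.22,4,-99,6.6,-72,9.7
14,47.61,-96.19,3,-102,9.6,-72,9.7
15,47.68,-96.20,18,-96,8.6,-73,9.7
16,48.14,-96.14,10,-79,7.1,-75,9.6
17,48.18,-96.72,5,-90,4.9,-74,9.6
18,47.26,-96.36,10,-75,6.7,-69,9.8
19,45.70,-94.32,8,-73,8.3,-64,9.9
20,44.99,-95.51,9,-61,5.9,-60,10.1
21,48.32,-104.49,4,-110,8.8,-85,9.7
22,48.58,-109.12,8,-124,7.6,-90,9.8
23,48.36,-107.99,9,-122,6.8,-88,9.8
24,45.93,-108.20,7,-118,9.2,-84,10.5
25,46.29,-107.24,7,-120,7.9,-84,10.4
26,46.27,-106.83,10,-122,7.9,-83,10.4
27,46.28,-104.41,8,-122,7.5,-83,10.0
28,46.42,-104.63,3,-123,1.1,-83,10.0
29,45.70,-104.33,3,-114,5.7,-82,10.0
30,46.79,-104.14,4,-124,7.9,-84,10.0
31,46.04,-104.37,6,-115,8.5,-83,10.0
32,46.50,-100.08,5,-93,2.8,-78,10.0
33,47.25,-100.58,3,-103,2.9,-81,10.0
34,47.32,-100.54,10,-102,3.5,-81,10.0
35,47.50,-100.49,10,-104,5.0,-82,9.9
36,48.01,-101.07,1,-122,,-23,
37,47.58,-101.05,3,-126,18.7,-19,5.2
38,47.59,-101.03,7,-120,7.0,-22,2.9
39,46.22,-100.04,6,-109,6.9,-20,3.6
40,46.27,-99.51,10,-115,8.0,-23,0.9
41,46.38,-99.44,7,-112,5.7,-23,3.2
42,46.50,-99.51,10,-111,7.8,-23,0.5
43,47.28,-99.51,5,-117,7.1,-25,1.4
44,44.78,-99.82,12,-105,10.2,-21,3.2
45,44.35,-100.01,3,-117,10.5,-26,6.5
46,44.80,-99.95,10,-99,9.2,-22,1.8
47,44.95,-99.92,7,-97,8.7,-22,2.1
48,44.69,-100.13,14,-90,11.2,-21,2.2
49,45.15,-100.00,4,-99,18.6,-22,2.0
50,45.53,-100.30,11,-107,11.5,-21,2.7
51,45.41,-99.94,4,-112,7.7,-22,2.8
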