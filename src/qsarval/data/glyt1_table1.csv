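id,ae,gamma,te,hbd,se,td,log10ic50,subset,outlier
2,41.05,40.3,12.9136,1,2.609,11,0.47712126,train,0
3,43.9,43.9,12.833,1,3.43,11,1.61278386,train,0
4,43.9,43.9,12.2837,1,3.7251,11,0.77815125,train,0
5,41.96,44.6,10.5041,1,3.3398,11,1.96378783,train,0
6,43.87,50.9,5.8562,1,3.5148,10,0,train,0
7,43.11,54.3,10.9678,1,3.5012,10,0.77815125,train,0
8,44.29,57.7,10.6827,1,3.31,10,0.47712126,train,0
10,43.05,49.2,13.6092,1,3.581,10,2.69372695,train,0
11,43.82,51.6,16.8366,1,3.7574,10,2.67577834,train,0
12,42.28,53.7,12.0135,1,3.2349,10,1.87506126,train,0
13,43.11,54.3,15.9864,1,3.5181,10,2.90794852,train,0
14,43.87,50.9,12.0765,1,3.6081,10,1.36172784,train,0
15,43.11,54.3,15.211,1,3.5393,10,1.65321251,train,0
17,45.28,46.3,11.4242,1,4.1245,10,0.77815125,train,0
18,46.55,43.3,11.1295,1,4.5556,11,2.53147892,train,0
19,45.81,43.2,11.5098,1,4.5198,11,2.71096312,train,0
20,46.95,45.7,12.3354,1,3.7527,11,0.95424251,train,0
21,45.81,43.2,11.5767,1,3.7965,11,1.462398,train,0
22,46.55,43.3,12.3649,1,4.0183,12,2.24797327,train,0
23,45.81,43.2,11.5647,1,3.7752,12,3.23121465,train,0
24,46.55,43.3,12.3272,1,3.9781,13,3.24526584,train,0
25,41.5,38.4,18.5378,1,3.5883,11,3.52659771,train,0
26,40.85,43.8,14.1068,1,3.3294,11,1.8920946,train,0
29,43.14,46.6,17.5352,1,3.5318,11,2.95616843,train,0
30,42.67,45.3,11.6496,1,3.2701,10,0,train,0
31,43.05,49.2,15.9695,1,3.5677,10,0,train,0
33,52.92,45,13.4879,1,3.9397,14,2.97589114,train,0
34,41.86,48.5,7.3285,2,2.3774,10,0.47712126,train,0
37,45.11,46,10.9824,1,3.3677,10,0,train,0
38,44.35,48.9,16.6401,1,3.3293,10,1,train,0
40,39.53,51.1,7.6774,2,2.2337,10,1.76342799,train,0
41,38.77,54.5,13.3491,2,2.2124,10,1.65321251,train,0
42,40.15,49.3,8.3209,1,3.3316,10,0.84509804,train,0
43,41.98,47.7,10.8208,1,3.622,10,0.47712126,train,0
44,38.2,52.2,5.2114,2,2.8062,10,2.22530928,train,0
1,45.25,41.3,39.2347,1,2.6809,13,1.56820172,test,1
9,43.81,46.2,10.3084,1,3.6309,10,0,test,0
16,43.6,55.2,8.802,2,3.3159,10,0.90308999,test,0
27,43.14,46.6,18.0072,1,3.6639,11,1.25527251,test,0
28,43.14,46.6,18.0105,1,3.682,11,2.32428246,test,0
32,53.84,50.1,58.0893,1,5.1759,14,0,test,1
35,41.48,47.3,9.0526,1,2.9116,10,0.47712126,test,0
36,43.31,45.9,9.4978,1,3.0768,10,0.60205999,test,0
39,44.32,54.8,9.9783,1,2.9,10,0.30103,test,0
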