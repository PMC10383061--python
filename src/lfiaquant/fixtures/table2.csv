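y1,concentration_ug_ml
0.0000,0
0.0000,0
0.0000,0
0.0000,0
0.0000,0
0.0774,5
0.0626,5
0.0927,5
0.0477,5
0.0116,5
0.1297,10
0.0824,10
0.0663,10
0.0367,10
0.0314,10
0.0873,30
0.1343,30
0.0829,30
0.1586,30
0.0967,30
0.1784,50
0.1438,50
0.1249,50
0.1584,50
0.1352,50
0.2187,80
0.1348,80
0.1857,80
0.1992,80
0.2375,80
0.4009,100
0.3498,100
0.2821,100
0.3389,100
0.6874,100
0.9596,300
0.9069,300
0.7958,300
0.8353,300
0.8599,300
1.0008,500
1.2781,500
1.3111,500
1.0767,500
0.9237,500
1.3142,800
1.4234,800
1.5778,800
1.3373,800
0.9765,800
1.4978,1000
1.4498,1000
1.4626,1000
1.6317,1000
1.1935,1000
1.9040,1300
2.0319,1300
1.5254,1300
1.4284,1300
1.2317,1300
1.7000,1500
2.0939,1500
1.6717,1500
1.6454,1500
1.3246,1500
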