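time_days,value_percent,sd_percent
10.5,0,0
16.5,0.3,0.2
17.5,0.4,0.4
18.5,12.1,1.4
19.5,7.9,0.8
21.5,17.4,1.9
24.5,37.8,1.1
29.5,45.4,2.4
31.5,46.5,3.3
33.5,57.2,4.5
35.5,60.4,3.9
38.5,64.7,4.3
40.5,72.0,5.6
73.5,88.3,5.1
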