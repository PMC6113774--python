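time_days,value_percent,sd_percent
10.5,75.1,1.4
16.5,46.5,6.4
17.5,52.8,2.8
18.5,51.0,2.0
19.5,30.8,4.8
21.5,13.5,1.6
29.5,2.3,1.4
41.5,1.5,0.4
59.5,0.69,0.1
69.5,0.44,0.04
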