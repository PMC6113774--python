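parameter,value
beta,0.3010
k2,1.0102
km2,0.6084
k3,0.0610
k4,0.2008
k6,0.0424
k7,0.8380
pf0,0.3530
qf0,0.1166
ecm0,0
t0,10.5
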