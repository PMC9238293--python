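# Simultaneous deep-muscle temperature and central femoral artery blood flow
# measured in the human leg during passive heat stress (Chiesa et al. 2016).
temperature_C,flow_L_min
34.9,0.31
36.2,0.53
37.0,0.86
37.6,1.24
38.3,1.22
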