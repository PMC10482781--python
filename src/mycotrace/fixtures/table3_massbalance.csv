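element,conc_free,conc_bearing,stock_free,stock_bearing,stock_difference,conc_fb,fb_amount
Ag,0.92,0.61,2.55,1.70,0.85,2.19,0.022
Cd,0.73,0.60,2.01,1.67,0.34,3.90,0.039
Rb,225,175,620,485,130,1025,10.2
K,10590,9135,29335,25300,4040,22245,220
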