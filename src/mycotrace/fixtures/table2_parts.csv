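site,part,weight_pct,weight_pct_sd
granite,stipe,40.7,13.2
granite,cap,29.1,4.8
granite,sporophore,30.2,16.5
amphibolite,stipe,29.7,8.6
amphibolite,cap,37.0,16.4
amphibolite,sporophore,33.3,12.6
serpentinite,stipe,37.4,6.8
serpentinite,cap,27.6,9.5
serpentinite,sporophore,35.1,10.2
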