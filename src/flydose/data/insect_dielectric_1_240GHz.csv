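frequency_Hz,eps_r,sigma_S_per_m
1000000000.0,44.37188881879246,1.3846300827886466
2450000000.0,43.163915423650295,2.019739992578749
3600000000.0,42.0,2.8
6000000000.0,39.22711978265656,4.9827631576541656
12000000000.0,32.01017976297433,11.79732277484347
24000000000.0,21.59343895309686,23.65098190831189
60000000000.0,10.97009986793147,39.393785870873714
90000000000.0,8.55155053739595,44.502147219454436
120000000000.0,7.449341180076049,47.50849626209054
240000000000.0,6.027364023415056,53.416657286622794
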