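awg_mvpp,power_w,isptp_wcm2,pneg_mpa
250,20.28,15690,10.92
275,26.45,20570,11.83
280,26.96,20940,11.90
285,27.53,21350,11.97
300,28.42,21980,12.09
325,32.06,24430,12.52
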