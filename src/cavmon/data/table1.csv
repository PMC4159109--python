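trial,awg_mvpp,power_w,isptp_wcm2,pneg_mpa,time_to_rupture_s
1,250,20.28,15690,10.92,29
2,250,20.28,15690,10.92,133
3,275,26.45,20570,11.83,27
4,275,26.45,20570,11.83,25
5,275,26.45,20570,11.83,
6,275,26.45,20570,11.83,
7,280,26.96,20940,11.90,
8,285,27.53,21350,11.97,14
9,285,27.53,21350,11.97,32
10,300,28.42,21980,12.09,55
11,300,28.42,21980,12.09,41
12,300,28.42,21980,12.09,60
13,300,28.42,21980,12.09,19
14,300,28.42,21980,12.09,133
15,300,28.42,21980,12.09,35
16,325,32.06,24430,12.52,55
17,325,32.06,24430,12.52,67
18,325,32.06,24430,12.52,42
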