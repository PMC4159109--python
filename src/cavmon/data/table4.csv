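pair,inactive_s,active_s,difference_s,vessel_type
1,282,300,18,subclavian
2,170,300,130,subclavian
3,151,131,-20,femoral
4,180,300,120,subclavian
5,144,167,23,femoral
6,189,155,-34,subclavian
7,173,300,127,subclavian
8,22,175,153,femoral
9,300,300,0,subclavian
10,180,300,120,subclavian
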