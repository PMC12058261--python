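age_start,age_end,rate_per_100k
20,25,2
25,30,9
30,35,26
35,40,60
40,45,125
45,50,190
50,55,240
55,60,310
60,65,370
65,70,410
70,75,350
75,80,390
80,85,420
85,90,440
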