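participant,gender,age,height_cm,weight_kg,bmi
1,M,28,179,82,25.6
2,M,34,189,86,24.1
3,F,27,173,63,21.1
4,F,23,160,52,20.3
5,M,24,180,72,22.2
6,F,27,181,74,22.6
7,M,40,173,82,27.4
8,F,67,167,70,25.1
9,F,36,160,52,20.3
10,M,67,193,78,20.9
11,F,26,155,60,25.0
12,M,42,180,75,23.2
13,M,24,192,101,27.4
14,M,35,179,80,24.8
15,M,59,170,80,27.7
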