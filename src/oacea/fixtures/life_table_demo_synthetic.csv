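age_from,age_to,annual_prob
45,50,0.0030
50,55,0.0046
55,60,0.0071
60,65,0.0110
65,70,0.0169
70,75,0.0261
75,80,0.0402
80,85,0.0619
85,90,0.0954
90,95,0.1469
95,100,0.2264
100,105,0.3488
105,110,0.5374
110,inf,1.0
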