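age_lo,age_hi,sex,proportion
40,45,F,0.08643317
45,50,F,0.08560087
50,55,F,0.07714963
55,60,F,0.06940265
60,65,F,0.05333248
65,70,F,0.04174403
70,75,F,0.03495742
75,80,F,0.0307318
80,85,F,0.02388117
85,90,F,0.01491773
40,45,M,0.08560087
45,50,M,0.08387221
50,55,M,0.07561304
55,60,M,0.06748191
60,65,M,0.05160382
65,70,M,0.03918305
70,75,M,0.03111595
75,80,M,0.02452142
80,85,M,0.015622
85,90,M,0.00723478
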