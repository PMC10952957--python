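# Synthetic additive EQ-5D-5L decrement table (NOT a published tariff).
# Utility = 1 - sum of decrements over dimensions 0-4 (mobility, self-care,
# usual activities, pain/discomfort, anxiety/depression) at levels 2-5.
dimension,level,decrement
0,2,0.04
0,3,0.07
0,4,0.16
0,5,0.27
1,2,0.04
1,3,0.06
1,4,0.15
1,5,0.20
2,2,0.03
2,3,0.05
2,4,0.13
2,5,0.19
3,2,0.05
3,3,0.08
3,4,0.25
3,5,0.43
4,2,0.06
4,3,0.12
4,4,0.27
4,5,0.45
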