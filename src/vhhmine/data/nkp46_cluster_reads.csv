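cluster_id,count_r0,count_r1,count_r2
1,0,942,2630
2,1,2790,2991
3,36,4964,4147
4,888,8573,11954
ALL,887881,1138880,754669
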