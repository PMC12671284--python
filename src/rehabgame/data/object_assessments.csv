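participant,object,sr_pre_pct,sr_post_pct,rt_pre_ms,rt_post_ms
1,coffee_mug,42,91,723,530
1,wine_glass,65,89,478,423
1,tennis_ball,51,68,792,697
2,coffee_mug,50,100,528,532
2,wine_glass,54,62,780,702
2,tennis_ball,33,100,771,421
3,coffee_mug,42,64,845,811
3,wine_glass,70,75,845,771
3,tennis_ball,61,73,794,805
4,coffee_mug,54,85,576,490
4,wine_glass,50,55,786,515
4,tennis_ball,66,80,784,725
5,coffee_mug,66,78,823,783
5,wine_glass,72,92,806,588
5,tennis_ball,56,72,760,722
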