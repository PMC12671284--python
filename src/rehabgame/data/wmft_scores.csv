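participant,fas_pre,fas_post,time_pre_s,time_post_s
1,19,28,119,71
2,19,34,118,84
3,13,27,73,62
4,12,28,104,71
5,9,23,89,65
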