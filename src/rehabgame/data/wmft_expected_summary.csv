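column,mean,sd
fas_pre,14,4
fas_post,28,4
fas_change,14,3
time_pre,101,20
time_post,71,8
time_change,30,14
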