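column,mean,sd
fas_change,14,3
time_change,30,14
sr_change,23,12
rt_change,105,44
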