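participant,measure,column,mean,sd
1,sr,pre,53,12
1,sr,post,83,13
1,sr,change,30,17
1,rt,pre,664,165
1,rt,post,550,138
1,rt,change,114,71
2,sr,pre,46,11
2,sr,post,87,22
2,sr,change,42,30
2,rt,pre,693,143
2,rt,post,552,142
2,rt,change,141,185
3,sr,pre,58,14
3,sr,post,71,6
3,sr,change,13,9
3,rt,pre,828,29
3,rt,post,796,22
3,rt,change,32,43
4,sr,pre,57,8
4,sr,post,73,16
4,sr,change,17,13
4,rt,pre,715,121
4,rt,post,577,129
4,rt,change,139,115
5,sr,pre,65,8
5,sr,post,81,10
5,sr,change,16,4
5,rt,pre,796,33
5,rt,post,698,100
5,rt,change,99,103
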