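participant,age_years,sex,stroke_type,duration_months,affected_side,hand_dominance
1,67,male,ischemic,24,left,right
2,68,male,ischemic,16,left,right
3,57,male,ischemic,12,left,right
4,43,female,ischemic,4,left,right
5,51,male,hemorrhagic,56,left,right
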