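actual,Normal,StageI,StageII,StageIII
Normal,130,0,1,0
StageI,9,9,4,1
StageII,1,1,17,4
StageIII,0,0,1,15
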