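actual,Normal,StageI,StageII,StageIII
Normal,44,3,0,0
StageI,7,20,3,0
StageII,0,3,12,0
StageIII,0,1,0,7
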