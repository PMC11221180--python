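metric,Normal,StageI,StageII,StageIII
precision,0.86,0.74,0.80,1.00
recall,0.94,0.67,0.80,0.88
f1,0.89,0.70,0.80,0.93
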