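metric,Normal,StageI,StageII,StageIII
precision,0.93,0.82,0.77,0.79
recall,0.99,0.41,0.74,0.94
f1,0.96,0.55,0.76,0.86
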