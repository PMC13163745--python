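patient_id,override_score,note
P5,3,Acute inflammatory state: concurrent fever (38 C) with markedly elevated CRP (44.7 mg/L)
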