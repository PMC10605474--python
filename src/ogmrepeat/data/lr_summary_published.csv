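patient_id,lr_median
Pt7,1192
Pt10,3363
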