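patient_id,read_id,repeats
Pt7,ccs_1,1160
Pt7,ccs_2,1224
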