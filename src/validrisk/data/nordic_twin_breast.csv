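age_band,frr_mz,frr_dz
<50,5.91,3.51
50-59,4.93,2.77
60-69,2.98,2.24
70-79,2.5,1.8
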