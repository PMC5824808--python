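patient_id,progressor,age_at_t1,months_between_timepoints
256-NP,False,57,91.3
391-P,True,60,75.1
437-NP,False,67,74.2
451-NP,False,69,72.8
740-P,True,53,18.8
848-P,True,36,2.8
852-P,True,72.8,26.7
911-NP,False,73.6,79.3
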