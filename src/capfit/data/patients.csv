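patient_id,brachial_systolic_mmHg,ankle_systolic_mmHg,abi,wound_area_cm2
A,160,100,0.6,3.978
B,140,160,1.14,0.357
C,150,200,1.33,6.038
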