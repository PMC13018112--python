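code,SDE_T0,SDE_T1,SDO_T0,SDO_T1
Foot,25,24,22,20
Lower limb (non-foot),7,12,3,5
Shoulder,0,20,2,3
Lumbopelvic region,9,14,7,5
Trunk,22,22,19,15
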