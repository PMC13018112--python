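# Published statistics for the packaged body-part count table, used as
# comparison values when replicating the contingency analysis.
# chi2(12) = 30.41, p = .002, Cramer's V = 0.20; z = adjusted standardized
# residuals per cell.
stat,cell,value
chi2,,30.41
df,,12
cramers_v,,0.20
z,Foot:SDE_T0,0.79
z,Foot:SDE_T1,-2.37
z,Foot:SDO_T0,1.02
z,Foot:SDO_T1,0.98
z,Lower limb (non-foot):SDE_T0,0.17
z,Lower limb (non-foot):SDE_T1,0.97
z,Lower limb (non-foot):SDO_T0,-1.30
z,Lower limb (non-foot):SDO_T1,-0.03
z,Shoulder:SDE_T0,-3.01
z,Shoulder:SDE_T1,4.83
z,Shoulder:SDO_T0,-1.65
z,Shoulder:SDO_T1,-0.91
z,Lumbopelvic region:SDE_T0,0.16
z,Lumbopelvic region:SDE_T1,0.54
z,Lumbopelvic region:SDO_T0,-0.11
z,Lumbopelvic region:SDO_T1,-0.73
z,Trunk:SDE_T0,0.88
z,Trunk:SDE_T1,-1.71
z,Trunk:SDO_T0,0.96
z,Trunk:SDO_T1,0.13
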