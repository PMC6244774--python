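patient_id,sex,age_years,histology,who_grade,idh1_status,codeletion_assessed,tumor_location,aed,tumor_volume_cm3,eor_percent,adjuvant_treatment,kps,time_weeks,event,oba_global_z,nlgn3_tier
P01,M,48,oligodendroglioma,II,mutant,unavailable,R-FrT,VPA,14.93,100,none,70,301,0,-1.85,low
P02,F,26,astrocytoma,III,mutant,non_codeleted,L-T,VPA,147.33,99,rt_plus_chemo,90,224,1,-1.49,low
P03,F,26,astrocytoma,III,wildtype,non_codeleted,R-Fr,VPA,35.02,93,rt_alone,100,321,0,-1.46,low
P04,M,41,oligoastrocytoma,II,mutant,unavailable,L-P,VPA,35.95,94,rt_alone,90,292,0,-0.84,low
P05,M,37,oligodendroglioma,III,mutant,codeleted,R-Fr,VPA,44.74,100,rt_plus_chemo,100,219,0,-0.69,high
P06,F,53,astrocytoma,II,unavailable,unavailable,L-T,LEV,94.65,98,rt_alone,100,265,1,-0.62,unavailable
P07,M,47,astrocytoma,III,wildtype,non_codeleted,R-P,none,41.30,76,rt_plus_chemo,100,54,1,-0.47,low
P08,F,28,oligodendroglioma,II,mutant,non_codeleted,L-T,LEV,61.51,97,none,100,66,1,-0.37,low
P09,M,28,astrocytoma,II,wildtype,unavailable,L-Fr,LEV,68.07,96,none,100,45,1,-0.26,low
P10,M,43,astrocytoma,II,mutant,unavailable,L-T,VPA,53.41,100,none,80,305,0,-0.24,low
P11,F,37,astrocytoma,II,mutant,unavailable,L-T,CBZ,107.14,100,none,100,65,1,-0.23,low
P12,M,36,oligodendroglioma,III,wildtype,codeleted,L-Fr,LEV,27.61,97,rt_alone,100,293,0,-0.15,high
P13,M,18,astrocytoma,II,mutant,unavailable,L-Fr,VPA,36.46,92,none,100,251,1,-0.14,low
P14,M,35,oligoastrocytoma,II,mutant,codeleted,R-P,LEV,52.85,100,none,100,29,1,-0.12,moderate
P15,M,30,astrocytoma,II,wildtype,unavailable,R-T,PHT+LEV,85.03,91,none,100,156,1,0.23,low
P16,M,46,GBM,IV,wildtype,unavailable,L-Fr,VPA,123.05,99,rt_plus_chemo,90,39,1,0.31,high
P17,M,27,astrocytoma,II,mutant,unavailable,L-P,VPA,48.54,92,none,90,93,1,0.33,low
P18,M,37,GBM,IV,unavailable,unavailable,L-Fr,LEV,56.44,100,rt_plus_chemo,100,87,1,0.46,unavailable
P19,F,48,astrocytoma,II,mutant,unavailable,R-T,VPA,72.42,100,none,100,106,1,0.50,moderate
P20,M,52,oligodendroglioma,II,mutant,codeleted,L-T,none,53.22,97,none,100,250,1,0.57,moderate
P21,M,58,oligodendroglioma,III,mutant,codeleted,L-Fr,LEV,35.20,100,rt_plus_chemo,90,200,0,0.74,moderate
P22,M,30,astrocytoma,II,unavailable,unavailable,L-Fr,PHT,35.27,100,none,90,54,1,1.69,unavailable
P23,M,46,oligoastrocytoma,II,mutant,unavailable,R-T,VPA,76.58,88,none,100,164,1,1.72,moderate
P24,M,50,astrocytoma,II,wildtype,unavailable,L-T,none,47.68,95,none,80,8,1,2.38,moderate
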