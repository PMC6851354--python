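patient_id,stage,modality,sites,affected_rate,nonaffected_rate,seizure_freq,ilae
P1,pre,scalp,"C4,O2,P4,T6",4.01,3.48,30,
P2,pre,scalp,"C3,F7,T3,T5",7.03,0.45,180,
P3,pre,scalp,"F4,F8,T4,T6",0.26,0.39,0.5,
P4,pre,scalp,"F4,F8,T4,T6",0.48,0.17,2,
P5,pre,scalp,"C3,F3,Fp1",1.68,0.34,8,
P6,pre,scalp,"C4,F8,T6",0.63,0.16,12,
P7,pre,scalp,"F7,C3,T3,T5",0.62,0.02,4,
P8,pre,scalp,"C4,F4,F8,Fp2",11.18,2.72,450,
P1,post,scalp,"C4,O2,P4,T6",0.43,0.18,0.2,3
P2,post,scalp,"C3,F7,T3,T5",3.57,0.85,180,5
P2b,post,scalp,"C3,F7,T3,T5",0.52,0.18,0,1
P3,post,scalp,"F4,F8,T4,T6",0.23,0.21,1,3
P4,post,scalp,"C4,F4,F8,T4",2.36,2.21,15,5
P5,post,scalp,"C3,F3,F7,Fp1",0.10,0.04,0,1
P6,post,scalp,"C4,F8,T4,T6",0.25,0.21,0,1
P7,post,scalp,"C3,F7,T3,T5",0.15,0.10,0,1
P9,post,scalp,"C4,F4,F8,Fp2",0.53,0.37,0,1
P10,post,scalp,"C4,F4,F8,Fp2",0.63,0.44,0.35,
P11,post,scalp,"O2,P4,T4,T6",0.08,0.07,0,1
P1,pre,ecog,,31.73,,,
P1,post,ecog,,4.62,,,
P8,pre,ecog,,4.17,,,
P8,post,ecog,,0.00,,,
P9,pre,ecog,,1.80,,,
P9,post,ecog,,0.00,,,
P10,pre,ecog,,2.79,,,
P10,post,ecog,,1.24,,,
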