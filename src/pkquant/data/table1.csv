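outcome,region,mean,sd,icc,absvar_pct,sem,md_pct
V_T (2TCM),FC,0.72,0.16,0.73,15,0.08,32
V_T (2TCM),GM,0.70,0.17,0.78,15,0.08,31
V_T (2TCM),HIP,0.72,0.19,0.66,21,0.11,44
V_T (2TCM),STR,0.76,0.17,0.44,18,0.13,46
V_T (2TCM),THAL,0.77,0.22,0.69,21,0.12,43
V_S (2TCM),FC,0.42,0.09,0.68,14,0.05,32
V_S (2TCM),GM,0.42,0.09,0.67,15,0.05,34
V_S (2TCM),HIP,0.45,0.10,0.35,21,0.08,51
V_S (2TCM),STR,0.44,0.10,0.23,23,0.09,58
V_S (2TCM),THAL,0.48,0.14,0.91,13,0.04,24
BP_ND (2TCM),FC,1.49,0.33,0.65,18,0.2,37
BP_ND (2TCM),GM,1.62,0.40,0.31,29,0.33,56
BP_ND (2TCM),HIP,2.02,0.77,-0.19,50,0.84,115
BP_ND (2TCM),STR,1.41,0.39,0.32,22,0.32,63
BP_ND (2TCM),THAL,1.79,0.67,-0.11,39,0.71,110
BP_ND (SRTM-SVCA4),FC,0.17,0.04,0.21,29,0.04,63
BP_ND (SRTM-SVCA4),GM,0.21,0.06,0.34,27,0.05,59
BP_ND (SRTM-SVCA4),HIP,0.17,0.09,-0.39,83,0.11,160
BP_ND (SRTM-SVCA4),STR,0.21,0.09,-0.12,59,0.09,120
BP_ND (SRTM-SVCA4),THAL,0.35,0.09,0.32,22,0.07,55
BP_ND (SRTMv-SVCA4),FC,0.15,0.09,-0.49,113,0.11,194
BP_ND (SRTMv-SVCA4),GM,0.22,0.10,0.04,62,0.1,122
BP_ND (SRTMv-SVCA4),HIP,0.17,0.08,-0.84,75,0.11,180
BP_ND (SRTMv-SVCA4),STR,0.20,0.10,0.79,38,0.04,60
BP_ND (SRTMv-SVCA4),THAL,0.36,0.12,-0.14,46,0.13,97
BP_ND (SRTM-CER),FC,-0.07,0.09,0.51,60,0.06,258
BP_ND (SRTM-CER),GM,-0.03,0.06,0.51,277,0.04,444
BP_ND (SRTM-CER),HIP,0.01,0.08,0.19,181,0.07,1920
BP_ND (SRTM-CER),STR,-0.02,0.17,-0.14,196,0.18,2963
BP_ND (SRTM-CER),THAL,0.09,0.06,0.67,494,0.04,112
SUV 40-60 min,FC,10.31,3.72,0.89,19,1.26,34
SUV 40-60 min,GM,10.44,3.55,0.87,19,1.3,34
SUV 40-60 min,HIP,10.43,3.36,0.82,19,1.43,38
SUV 40-60 min,STR,10.27,3.64,0.80,26,1.63,44
SUV 40-60 min,THAL,11.36,3.81,0.84,20,1.55,38
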