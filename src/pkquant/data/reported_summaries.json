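{
  "median_icc": {
    "SUV 40-60 min": 0.84,
    "V_T (2TCM)": 0.69,
    "V_S (2TCM)": 0.67,
    "BP_ND (SRTM-SVCA4)": 0.21,
    "BP_ND (SRTMv-SVCA4)": -0.14
  },
  "median_md_pct": {
    "SUV 40-60 min": 38,
    "V_T (2TCM)": 43,
    "V_S (2TCM)": 34,
    "BP_ND (SRTM-CER)": 444
  },
  "bpnd_region_mean_ratio": {
    "2TCM_over_SRTM-SVCA4": 7,
    "2TCM_over_SRTM-CER": 700
  }
}
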