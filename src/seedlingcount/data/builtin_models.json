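{
  "format_version": 1,
  "stage_models": [
    {"variety": "YM23", "stage": 1, "coef_Ha": 0.47, "coef_Co": 119.37, "intercept": 5.65},
    {"variety": "YM23", "stage": 2, "coef_Ha": 0.22, "coef_Co": 58.64, "intercept": 18.43},
    {"variety": "YM23", "stage": 3, "coef_Ha": 0.15, "coef_Co": 37.65, "intercept": 14.73},
    {"variety": "HM7", "stage": 1, "coef_Ha": 0.41, "coef_Co": 97.13, "intercept": 11.37},
    {"variety": "HM7", "stage": 2, "coef_Ha": 0.19, "coef_Co": 43.93, "intercept": 6.94},
    {"variety": "HM7", "stage": 3, "coef_Ha": 0.13, "coef_Co": 31.05, "intercept": 17.72},
    {"variety": "YF4", "stage": 1, "coef_Ha": 0.52, "coef_Co": 125.21, "intercept": 2.71},
    {"variety": "YF4", "stage": 2, "coef_Ha": 0.25, "coef_Co": 59.35, "intercept": 6.21},
    {"variety": "YF4", "stage": 3, "coef_Ha": 0.16, "coef_Co": 39.11, "intercept": 11.51}
  ],
  "unified_model": {
    "a": 0.44,
    "b": 110.43,
    "c": 3.35,
    "d": 1.11,
    "variety_table": {"YM23": 1.05, "HM7": 0.86, "YF4": 1.12}
  }
}
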