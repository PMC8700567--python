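{
  "pediatric_inspiratory_v1": {
    "description": "Reference equations for inspiratory chest-CT densitometry in children aged 6-17 years (n = 80). Responses: total CT lung capacity (mL), mean lung attenuation (HU), low/high attenuation thresholds (HU), and percent of lung volume below/above the subject-specific thresholds.",
    "equations": {
      "tlc_vs_age": {
        "form": "linear",
        "response": "tlc_ct_mL",
        "predictor": "age_years",
        "intercept": -541.7,
        "coefficient": 319.7,
        "r_squared": 0.59,
        "n": 80
      },
      "mean_hu_vs_age": {
        "form": "inverse",
        "response": "mean_hu",
        "predictor": "age_years",
        "intercept": -892.8,
        "coefficient": 1160.4,
        "r_squared": 0.48,
        "n": 80
      },
      "lat_vs_age": {
        "form": "inverse",
        "response": "lat_hu",
        "predictor": "age_years",
        "intercept": -1018.5,
        "coefficient": 1034.1,
        "r_squared": 0.42,
        "n": 80
      },
      "hat_vs_age": {
        "form": "inverse",
        "response": "hat_hu",
        "predictor": "age_years",
        "intercept": -767.2,
        "coefficient": 1286.7,
        "r_squared": 0.50,
        "n": 80
      },
      "pct_high_vs_age": {
        "form": "inverse",
        "response": "pct_high",
        "predictor": "age_years",
        "intercept": 8.147,
        "coefficient": 26.931,
        "r_squared": 0.49,
        "n": 80
      },
      "pct_low_vs_tlc": {
        "form": "inverse",
        "response": "pct_low",
        "predictor": "tlc_ct_mL",
        "intercept": -0.561,
        "coefficient": 5876.6,
        "r_squared": 0.47,
        "n": 80
      },
      "pct_high_vs_tlc": {
        "form": "inverse",
        "response": "pct_high",
        "predictor": "tlc_ct_mL",
        "intercept": 8.771,
        "coefficient": 4875.9,
        "r_squared": 0.76,
        "n": 80
      }
    }
  }
}
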