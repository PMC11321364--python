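{
  "schema_version": 1,
  "curves": {
    "commercial": {
      "intercept": 110.0,
      "slope": -25.0
    },
    "light": {
      "intercept": 109.0,
      "slope": -25.95
    },
    "moderate": {
      "intercept": 109.2,
      "slope": -32.69
    },
    "dark": {
      "intercept": 110.6,
      "slope": -50.31
    }
  },
  "cohort_printed_mean_bias": {
    "white": 0.5,
    "black": 3.3
  },
  "cohort_printed_bias_ratio": 6.6
}
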