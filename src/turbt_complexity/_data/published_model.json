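{
  "provenance": "published",
  "description": "Published logistic regression of panel-judged TURBT complexity on the five predictor domain scores. Off-diagonal covariance terms were not published; the covariance matrix is the diagonal of the squared standard errors.",
  "domain_order": ["history", "number", "location", "size", "access"],
  "intercept": -13.34,
  "intercept_std_error": 2.31,
  "coefficients": {
    "history": 0.99,
    "number": 0.96,
    "location": 1.44,
    "size": 1.04,
    "access": 1.10
  },
  "std_errors": {
    "history": 0.32,
    "number": 0.23,
    "location": 0.33,
    "size": 0.26,
    "access": 0.26
  },
  "n_obs": 131
}
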