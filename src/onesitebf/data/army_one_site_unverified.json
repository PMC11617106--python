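{
  "_comment": "PLACEHOLDER coefficients, UNVERIFIED. The official one-site equation coefficients are published in service regulation tables (AR 600-9) and must be transcribed from the regulation and this file updated (verified: true) before any operational use. These placeholders are order-of-magnitude plausible so the pipeline runs end to end, nothing more.",
  "name": "army-one-site-UNVERIFIED-placeholder",
  "intercept_male": -26.0,
  "coef_mass_male": -0.12,
  "coef_circ_male": 1.6,
  "intercept_female": -10.0,
  "coef_mass_female": -0.16,
  "coef_circ_female": 1.5,
  "mass_unit": "lb",
  "circ_unit": "in",
  "rounding_rule": "none",
  "verified": false
}
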