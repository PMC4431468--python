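# SYNTHETIC placeholder for the conventional (Caucasian-reference) CVD risk
# scheme.  The published boundary coefficients were never printed in numeric
# form, so this file carries stand-in values with the same structure; it
# exercises the scheme machinery and the scheme-comparison code paths but
# carries no clinical meaning.  Supply your own coefficients to compare
# against a real conventional scheme.
name: conventional_synthetic_placeholder
sr_threshold: 10.0
multipliers: [1.0, 2.0]
strata:
  men:
    mean_intercept: 0.83
    mean_slope: 0.024
    sd_intercept: 0.30
    sd_slope: 0.0
    age_domain: [18, 80]
  women_low_sr:
    mean_intercept: 0.83
    mean_slope: 0.024
    sd_intercept: 0.30
    sd_slope: 0.0
    age_domain: [18, 80]
  women_high_sr:
    mean_intercept: 0.83
    mean_slope: 0.024
    sd_intercept: 0.30
    sd_slope: 0.0
    age_domain: [18, 80]
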