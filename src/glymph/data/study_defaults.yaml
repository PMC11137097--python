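# Default cohort-generator parameters: group demographics/biomarker moments
# and the pooled regression links tying every biomarker to the amyloid
# (centiloid) axis.  These are the shipped study conditions; override any
# block in a scenario file to simulate a different population.
groups:
  CN: {n: 27, n_male: 11, age_mean: 69.3, age_sd: 9.6, centiloid_mean: 0.4, centiloid_sd: 6.7}
  AD: {n: 56, n_male: 28, age_mean: 69.9, age_sd: 10.6, centiloid_mean: 78.5, centiloid_sd: 33.4}
# ALPS = intercept + slope * centiloid + residual; r is the pooled Pearson
# correlation the residual variance is solved from.
alps_links:
  b1000: {slope: -0.0018, intercept: 1.436, r: 0.65}
  b2000: {slope: -0.0014, intercept: 1.386, r: 0.47}
# ALPS(b=1000) = intercept + slope * MMSE (ALPS as response); inverted to
# generate MMSE from ALPS.
mmse_link: {slope: 0.017, intercept: 0.902, r: 0.55}
# VSRAD Z = intercept + slope * ALPS(b=1000) (VSRAD as response).
vsrad_link: {slope: -2.65, intercept: 5.16, r: 0.40}
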