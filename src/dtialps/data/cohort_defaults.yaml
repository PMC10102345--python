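# Default cohort-simulation parameters: 20 ischemic-stroke (IS) subjects vs
# 30 healthy controls (HC), with the published ALPS group means/SDs and the
# targeted ALPS–motor and ALPS–CST correlations in the IS group.
# Diffusivities (cst_md_*) are mm²/s; ALPS is unitless; ages in years.
n_is: 20
n_hc: 30
is_group:
  male_fraction: 0.80
  means:
    alps_left: 1.424
    alps_right: 1.381
    fma_motor: 80.0
    fma_sensory: 20.0
    cst_fa_left: 0.52
    cst_fa_right: 0.55
    cst_md_left: 0.00080
    cst_md_right: 0.00075
    cc_fa_left: 0.65
    cc_fa_right: 0.65
    age: 59.2
    days_post_onset: 14.0
  sds:
    alps_left: 0.132
    alps_right: 0.172
    fma_motor: 20.0
    fma_sensory: 4.0
    cst_fa_left: 0.05
    cst_fa_right: 0.05
    cst_md_left: 0.00006
    cst_md_right: 0.00006
    cc_fa_left: 0.05
    cc_fa_right: 0.05
    age: 12.1
    days_post_onset: 8.0
  correlations:
    - {a: alps_left, b: fma_motor, r: 0.5}
    - {a: alps_left, b: cst_fa_right, r: -0.55}
    - {a: alps_left, b: cst_md_right, r: -0.45}
    - {a: alps_left, b: fma_sensory, r: 0.4}
hc_group:
  male_fraction: 0.6667
  means:
    alps_left: 1.565
    alps_right: 1.454
    cst_fa_left: 0.56
    cst_fa_right: 0.56
    cst_md_left: 0.00072
    cst_md_right: 0.00072
    cc_fa_left: 0.66
    cc_fa_right: 0.66
    age: 54.6
  sds:
    alps_left: 0.197
    alps_right: 0.107
    cst_fa_left: 0.04
    cst_fa_right: 0.04
    cst_md_left: 0.00005
    cst_md_right: 0.00005
    cc_fa_left: 0.04
    cc_fa_right: 0.04
    age: 7.4
  correlations:
    - {a: alps_left, b: alps_right, r: 0.4}
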