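# Default NTCP parameter registry, keyed by organ.
# hippocampus: LKB probit on EQD2(D40%), alpha/beta = 2 Gy (neurocognitive impairment)
# scalp:       LKB probit on gEUD with volume exponent n (acute grade-2 alopecia)
# hpa:         multivariate parametric endocrine-dysfunction model (age, dose, follow-up)
# cochlea:     logistic regression on median cochlear dose (hearing loss)
hippocampus:
  model: lkb
  TD50_Gy: 14.88
  m: 0.54
scalp:
  model: lkb
  TD50_Gy: 22.0
  m: 0.54
  n: 0.14
hpa:
  model: endocrine
  gamma: 0.56
  const: 3.13
  beta_age: -0.106
  beta_age2: 0.007
  beta_dose: -0.049
  t_years: 5.0
cochlea:
  model: logistic
  b0: -5.3
  b1: 0.085
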