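# Synthetic stand-in stimulus-curve families for full-scale volume-overload
# scenarios. The geometry families (LVM, VED) are anchored at the reported
# steady-state fold changes of canine mitral regurgitation (mass ~1.36-fold,
# end-diastolic volume ~1.67-fold), with amplitude spreads chosen once from
# the reported ensemble interval widths; the hormone families are plausible
# saturating/peaking fold-change curves, NOT fits to the original digitized
# source data (which this package does not ship). Parameter layout matches
# vonet.input_curves.CurveFamily: saturating_exp -> [A, theta] for
# 1 + A(1 - exp(-t/theta)); peak_decay -> [A, theta] for
# 1 + A (t/theta) exp(1 - t/theta); t in t/tau units.
LVM:
  form: saturating_exp
  param_mean: [0.36, 1.0]
  param_cov: [[0.04, 0.0], [0.0, 0.04]]
  domain: [0.0, 5.0]
VED:
  form: saturating_exp
  param_mean: [0.67, 0.15]
  param_cov: [[0.0625, 0.0], [0.0, 0.0009]]
  domain: [0.0, 5.0]
AngII:
  form: saturating_exp
  param_mean: [0.8, 0.6]
  param_cov: [[0.16, 0.0], [0.0, 0.01]]
  domain: [0.0, 5.0]
NE:
  form: saturating_exp
  param_mean: [1.5, 0.8]
  param_cov: [[0.49, 0.0], [0.0, 0.04]]
  domain: [0.0, 5.0]
ET1:
  form: saturating_exp
  param_mean: [1.0, 1.0]
  param_cov: [[0.25, 0.0], [0.0, 0.04]]
  domain: [0.0, 5.0]
ANP:
  form: peak_decay
  param_mean: [2.0, 0.5]
  param_cov: [[0.5625, 0.0], [0.0, 0.01]]
  domain: [0.0, 5.0]
BNP:
  form: peak_decay
  param_mean: [1.5, 0.8]
  param_cov: [[0.36, 0.0], [0.0, 0.04]]
  domain: [0.0, 5.0]
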