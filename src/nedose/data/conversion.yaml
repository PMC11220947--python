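# Dose-reporting conversion constants.
#
# formulations: multiplicative factor c_f turning a norepinephrine BASE-molecule
# dose (ug/kg/min) into the numerically equivalent dose reported as that salt:
#     reported_salt_dose = base_dose * c_f
# Factors are stored to the printed precision used in the critical-care
# literature; no extra chemistry-derived digits.
formulations:
  base: 1.0
  hydrochloride: 1.22
  bitartrate: 1.89
  tartrate: 2.0

# ne_equivalent_weights: weights for collapsing a multi-vasopressor regimen
# into a single norepinephrine-equivalent rate (ug/kg/min).  Transcribed from
# the updated vasopressor-equivalence formulas of Kotani et al. (Crit Care
# 2023; doi:10.1186/s13054-023-04322-y):
#     NEE = NE + EPI + PHE/10 + DOP/100 + MET/8 + VAS*2.5 + ANG2*10
# Each weight applies to the drug's NATIVE rate unit given below; rates
# supplied in any other unit are rejected, never silently converted.
ne_equivalent_weights:
  norepinephrine: {weight: 1.0, unit: ug/kg/min}
  epinephrine: {weight: 1.0, unit: ug/kg/min}
  phenylephrine: {weight: 0.1, unit: ug/kg/min}
  dopamine: {weight: 0.01, unit: ug/kg/min}
  metaraminol: {weight: 0.125, unit: ug/kg/min}
  vasopressin: {weight: 2.5, unit: U/min}
  angiotensin_ii: {weight: 10.0, unit: ug/kg/min}
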