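# Reference parameter set for the CSSTRESAC tumor-growth / PK model.
#
# Entries marked [study] are values stated directly by the study design
# (doses, carrying capacity, soluble-peptide clearance). Entries marked
# [placeholder] are reconstructed reference values: the fitted parameter
# table they mirror is not publicly printed, so these were chosen once to
# be physiologically plausible for the mouse mammary-tumor system and to
# reproduce the model's published predictions (see docs/methods.md for the
# derivation). Replace them with fitted values from your own cohort via the
# calibration pipeline.
parameters:
  sigma: 0.15          # day^-1, tumor growth rate constant [placeholder]
  K: 1.0e4             # mm^3, carrying capacity [study]
  V0: 250.0            # mm^3, volume at implantation (t=0) [placeholder]
  D_pep: 0.012         # day^-1, asymptotic peptide-induced death rate [placeholder]
  Kd: 0.75             # mM, CSSTRESAC-DBP-PDIA3 dissociation constant [placeholder]
  lam: 25.0            # day^-1 per mg/mm^3, GCV kill proportionality [placeholder]
  kex_pep: 0.35        # day^-1, AAVP-displayed peptide excretion [placeholder]
  kex_pep_sol: 38.0    # day^-1, soluble peptide excretion (t1/2 ~ 26 min) [study]
  ka_gcv: 12.0         # day^-1, GCV peritoneal absorption [placeholder]
  kex_gcv: 3.0         # day^-1, GCV renal excretion [placeholder]

schedule:
  peptide_bolus_day: 5.0
  peptide_bolus_mM: 0.8       # I1 [study]
  gcv_days: [12, 13, 14, 15, 16, 17, 18, 19, 20, 21]
  gcv_dose_mg_per_mm3: 0.008  # I0 = 80 mg/kg/day, 20 g mouse, 10 ml/kg [study]

trial:
  infusion_mu: 0.75    # mM, asymptotic infusion concentration [study]
  bolus_amount: 1.0    # mM, "unit" iv bolus (design choice)
  infusion_start: 5.0  # day
  horizon: 60.0        # day, projection end (design choice)
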