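# Methods

## Model

The package implements a deterministic growth/death balance for tumor volume
V(t) coupled to one-compartment pharmacokinetics of two agents: the
TAM-targeting peptide CSSTRESAC (iv, either displayed on an AAVP vector or
soluble) and ganciclovir (ip). The assumptions are those of the classical
logistic tumor-kill family:

* the tumor is a well-mixed volume; spatial structure, vasculature and
  immune-cell populations are not modelled explicitly — TAM repolarisation by
  the peptide enters only through the saturable kill term;
* peptide kill saturates in concentration (receptor occupancy): per-volume
  death rate D_pep·C/(C + K_d), with half-maximal kill at C = K_d and
  asymptote D_pep; competitive antagonism by circulating 1,25-(OH)₂D₃ is not
  given a functional form — the model exposes K_d directly and probes
  antagonism by perturbing it ±20 %, since no competition constant is
  identifiable from tumor-volume data alone;
* GCV kill is linear in plasma concentration and active only where the HSVtk
  transgene was delivered (both AAVP arms, not the GCV-only control);
* drug kinetics are first order; dosing is impulsive (exact state jumps at
  dose times) or a constant-rate infusion whose source term μ·k_ex makes the
  infusion constant μ the asymptotic plasma concentration.

**Death-term scaling.** Written as absolute rates, the kill expressions have
units of day⁻¹ and cannot be subtracted from a mm³/day growth term. The
default therefore treats them as per-volume rates multiplied by V, the
convention of the logistic tumor-kill lineage this model belongs to; a
`death_term_scaling="absolute"` switch preserves the literal absolute-rate
reading for comparison (in that mode non-negativity of V is enforced by
clamping at zero rather than by structure).

**Units.** Volume mm³, time days, peptide in mM, GCV in mg/mm³. The systems
are unit-opaque: only products of a concentration with its paired rate
constant enter dV/dt, so no conversion between the two drug unit systems is
needed (and none would be identifiable). The plasma volume of distribution
of GCV is likewise not separately identifiable and is folded into k_a/λ;
`fit_gcv_pk` co-estimates a free amplitude scale for the same reason.

## Reference parameters

`src/tumorpkpd/data/default_params.yaml` carries the study-stated quantities
(K = 10⁴ mm³; k_ex,sol = 38 day⁻¹; I₀ = 0.008 mg/mm³; I₁ = 0.8 mM;
μ = 0.75) verbatim. The remaining entries are reconstructed reference values,
chosen once, analytically, to be physiologically plausible and to reproduce
the model's published predictions:

* σ = 0.15 day⁻¹, V₀ = 250 mm³ — gives control-arm volumes of ≈ 2000 mm³ at
  day 15 and ≈ 3700 mm³ at day 21, the caliper scale of the mouse
  experiments, and keeps the day 15–21 σ-fitting window on the informative
  part of the logistic curve;
* D_pep = 0.012 day⁻¹ with K_d = 0.75 mM — at the 60-day projection horizon
  both trial arms approach their asymptotes, so the bolus-infusion volume
  difference tends to K·s/σ with s = D_pep·μ/(μ + K_d); requiring ≈ 400 mm³
  fixes s = 0.04·σ, and K_d was set at the infusion concentration
  (half-saturation at μ = 0.75);
* λ = 25 day⁻¹ per mg/mm³ — a mean GCV kill of ≈ 0.07 day⁻¹ during the
  dosing window, a clear but not overwhelming growth delay in the fd-AAVP
  arm;
* k_a = 12, k_ex,GCV = 3 day⁻¹ — fast ip absorption, plasma half-life a few
  hours; k_ex,pep = 0.35 day⁻¹ — the vector-displayed peptide persists for
  days, unlike the soluble form.

These defaults are the ground truth of the synthetic generator and the
parameter set of the simulated trial; they are not refit or revisited by the
test suite.

## Synthetic data

`generate_cohort` emulates the experimental design: six arms (vehicle,
unrelated control peptide, soluble CSSTRESAC, GCV-only control,
fd-AAVP-HSVtk + GCV, CSSTRESAC-AAVP-HSVtk + GCV), n = 10 subjects per arm,
caliper measurements on days 15, 17, 19, 21 (one week after treatment
initiation, then every other day). Each subject is the arm's deterministic
model trajectory perturbed by independent multiplicative lognormal noise
(CV 10 %, mean-one), reflecting size-proportional caliper error and
guaranteeing positive volumes. The soluble-peptide arm assumes daily iv
boluses on days 5–21. `generate_gcv_pk_samples` emulates a digitized plasma
curve after a single ip dose: eight log-spaced samples over 12 h on the
Bateman curve.

What the generator does **not** emulate: between-subject growth
heterogeneity (random effects), serial correlation within a subject,
measurement dropout/sacrifice, or model misspecification. Passing the
recovery tests therefore demonstrates that the estimation machinery inverts
the model correctly under its own assumptions — not that the model is
correct for real animals.

## Calibration

Stages run strictly in sequence, each consuming only previously estimated
parameters (matching the experimental information structure). All stages fit
per-day arm means by ordinary least squares (the figures the data come from
report mean ± SD; an inverse-variance option weights by 1/SD² when SDs are
available), using SciPy's bounded trust-region reflective least squares.

* σ stage: fits (σ, anchor volume at the first window day) of the logistic
  closed form on all control observations in days [15, 21]; bounds
  σ ∈ (0, 5]. V₀ then follows in closed form by backward extrapolation from
  the fitted anchor.
* GCV PK stage: Bateman fit with heuristic starts (terminal log-slope for
  k_ex, peak position for k_a) plus two dispersed restarts. The
  absorption/excretion exchange ambiguity is resolved by the convention
  k_a > k_ex; a fit landing on the mirror branch is relabelled with the
  amplitude rescaled so the curve is unchanged.
* λ stage: single-parameter fit, bounds [0, 10³], four log-spaced starts;
  a solution at the upper bound is flagged as non-converged.
* Peptide stage: (D_pep, K_d, k_ex,pep) fitted jointly in log₁₀ space with
  8 Latin-hypercube starts (seed configurable, default 20210601); bounds
  D_pep ∈ [0, 10³], K_d, k_ex ∈ (0, 10³]. When the fitted K_d lies far above
  the peak plasma concentration only D_pep/K_d is identified and the result
  is flagged; recovery is then guaranteed at curve level (trajectory RMSE),
  not per coordinate.
* Soluble stage: k_ex,sol alone, log-parameterised, (D_pep, K_d) fixed from
  the gene-therapy fit, λ absent (no GCV in that experiment).

Fit quality is the Pearson correlation between model predictions and
observed arm means at the observation days, with its two-sided p-value.

**Identifiability.** At the reference effect sizes, σ, V₀, λ, k_a and
k_ex,GCV are practically identifiable under 10 % observation noise (median
bias well under 15 % over 100 simulated cohorts). k_ex,sol is exactly
recoverable from noise-free data but *not* practically identifiable under
noise: a drug with a 26-minute half-life dosed once daily is present for
≈ 1/40 of each day, so its cumulative imprint on the tumor curve (≈ 1 % of
volume at the reference potency) is far below the noise floor of day-mean
volumes. This is a structural property of the design, worth knowing before
attempting such a fit on real data, and is why the noise-robustness test
asserts bias bounds only for the identifiable set.

## Numerics

LSODA (implicit-capable, adaptive) with rtol 1e-8, atol 1e-10; the soluble
peptide compartment (k_ex = 38 day⁻¹) is fast relative to tumor dynamics,
which is what motivates a stiffness-switching method. Integration restarts
at every dose event and at the infusion switch-on, applying doses as exact
state jumps — no event-finding. Output is sampled on a 0.1-day grid (or any
requested day set); a dose falling exactly on the horizon is reported
post-jump, matching the convention at interior dose times. Tiny negative
excursions are clamped to zero at segment boundaries. V = 0 and V = K are
valid absorbing/equilibrium states, not errors.

## Trial simulation choices

The "unit" bolus of the human-trial comparison is 1 concentration unit
(1 mM) administered at the infusion start day (day 5); both the amount and
the 60-day projection horizon are exposed settings (`bolus_amount`,
`horizon`). The ≈ 400 mm³ bolus-vs-infusion difference is insensitive to the
bolus amount (a soluble bolus of any plausible size clears within an hour)
and, past day ~45, to the horizon, because both arms have then essentially
reached their asymptotes K and K(1 − s/σ).

## Known limitations

* Population-mean fitting only; no mixed-effects or Bayesian machinery.
* No allometric scaling: the simulated human trial reuses mouse-calibrated
  parameters unchanged.
* The GCV-only control arm is modelled as pure logistic growth (GCV without
  HSVtk is assumed inert at these doses).
* The reconstructed default parameters are reference values for simulation
  and benchmarking, not fitted estimates from animal data.
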