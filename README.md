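# tumorpkpd

Mechanistic pharmacokinetic–pharmacodynamic (PK/PD) modelling of mammary-tumor
growth under two therapies built around CSSTRESAC, a cyclic nine-residue
peptide that targets PDIA3-expressing tumor-associated macrophages (TAM):

* **ligand-directed suicide gene therapy** — the peptide displayed on an
  AAVP (adeno-associated virus/phage) vector delivers the HSVtk gene,
  activated by daily intraperitoneal ganciclovir (GCV);
* **systemic treatment with the soluble peptide**, including a simulated
  human trial comparing a unit iv bolus against constant-rate infusion.

The package is aimed at modellers who want to calibrate this model family to
longitudinal caliper measurements (arm / subject / day / volume), explore
dose regimens in silico, or benchmark estimation procedures on synthetic
cohorts with known ground truth.

## The model

Tumor volume V (mm³) obeys a growth/death balance

    dV/dt = G − S − N
    G = σ·V·(1 − V/K)                      logistic proliferation
    S = V·D_pep·C_pep/(C_pep + K_d)        saturable peptide kill
    N = V·λ·C_gcv                          GCV kill (linear in plasma conc.)

where σ is the growth rate constant (day⁻¹), K the carrying capacity
(10⁴ mm³), D_pep the asymptotic peptide-induced death rate (potency), K_d the
dissociation constant of the CSSTRESAC–DBP–PDIA3 complex (implicitly shifted
by competitive antagonism from 1,25-(OH)₂D₃), and λ the GCV kill
proportionality. Drug concentrations follow one-compartment first-order
kinetics with impulsive dosing:

    dC_pep/dt   = I(t) − k_ex·C_pep        iv peptide (bolus and/or infusion)
    dC_gcv/dt   = k_a·C_ip − k_ex,GCV·C_gcv   plasma GCV
    dC_ip/dt    = −k_a·C_ip                peritoneal GCV depot

with jumps C_ip → C_ip + I₀ at each daily GCV dose (I₀ = 0.008 mg/mm³,
i.e. 80 mg/kg in a 20 g mouse with a 10 ml/kg peritoneal cavity) and
C_pep → C_pep + I₁ at the vector bolus (I₁ = 0.8 mM, day 5). The infusion
source I(t) = μ·k_ex,sol (t > start) drives C_pep to the asymptote μ. The
displayed and soluble peptides clear at very different rates (k_ex,pep vs
k_ex,sol = 38 day⁻¹, half-life ln 2/38 ≈ 26 min).

Calibration is sequential, mirroring the staged experimental design: σ from
the GCV-only control arm (days 15–21), V₀ by backward extrapolation to
implantation, (k_a, k_ex,GCV) from plasma GCV after an ip dose (Bateman
curve), λ from the fd-AAVP-HSVtk + GCV arm, (D_pep, K_d, k_ex,pep) jointly
from the CSSTRESAC-AAVP-HSVtk + GCV arm, and k_ex,sol refit on the
soluble-peptide arm. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

```python
from tumorpkpd import TumorGrowthModel, default_parameters
from tumorpkpd.synthetic import NoiseModel, generate_cohort, generate_gcv_pk_samples

truth = default_parameters()
cohort = generate_cohort(truth, noise=NoiseModel(kind="none"))
pk_data = generate_gcv_pk_samples(truth.ka_gcv, truth.kex_gcv, 0.008,
                                  noise=NoiseModel(kind="none"))

results = TumorGrowthModel(cohort, gcv_pk=pk_data).fit()
print(results.summary())
```

prints

```
Sequential tumor-growth model calibration
=========================================================
parameter           estimate  stage
---------------------------------------------------------
sigma                   0.15  fit_growth_rate
K                      10000  fixed (literature)
V0                       250  extrapolate_initial_volume
D_pep              0.0120055  fit_peptide_params
Kd                  0.750573  fit_peptide_params
lam                       25  fit_gcv_death
kex_pep             0.349969  fit_peptide_params
kex_pep_sol          37.9978  refit_soluble_excretion
ka_gcv                    12  fit_gcv_pk
kex_gcv                    3  fit_gcv_pk
---------------------------------------------------------
Pearson R (treated arm) = 1.0000 (p = 0)
total RSS = 1.69472e-08   converged = True
```

— the calibration recovers the generating parameters of the noise-free
cohort essentially exactly (growth rate 0.15 day⁻¹, implantation volume
250 mm³, GCV kill 25 day⁻¹ per mg/mm³, soluble clearance 38 day⁻¹ ⇒
half-life ≈ 26 min), with a treated-arm Pearson R of 1 as expected on
self-generated data. From the fitted object:

```python
results.compare_bolus_vs_infusion(mu=0.75, horizon=60.0)  # ≈ 413 mm³
results.kd_sensitivity()   # {'-20%': 9492.7, 'ref': 9538.8, '+20%': 9576.5}
```

the infusion regimen leaves the tumor ≈ 400 mm³ smaller than a unit bolus at
the projection horizon, and perturbing K_d by ±20 % orders the final volumes
exactly as competitive antagonism predicts (weaker binding → larger tumor).

A command-line pipeline wraps the same functionality:

```bash
tumorpkpd --seed 7 --out run/ synth          # synthetic cohort + PK samples
tumorpkpd --out run/ fit --cohort run/cohort.csv --pk run/gcv_pk.csv
tumorpkpd --out run/ trial --mu 0.75 --horizon 60
tumorpkpd --out run/ sensitivity
tumorpkpd --out run/ report                  # everything, end to end
```

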