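# vaptmdd

Population pharmacokinetic–pharmacodynamic modelling of **ASP8232**, a small-
molecule inhibitor of vascular adhesion protein-1 (VAP-1), for scientists who
need to simulate exposure and VAP-1 inhibition in diabetic kidney disease
(DKD) populations, explore dose regimens, or test estimation methodology on
realistic synthetic trial data.

VAP-1 circulates as soluble protein (sVAP-1) and sits membrane-bound
(mVAP-1) in tissues; ASP8232 binds both with a single dissociation constant
K_D ≈ 0.93 nM. Because the target pools are comparable in size to the drug
concentrations at low doses, binding feeds back on drug disposition — a
*target-mediated drug disposition* (TMDD) system. The package implements the
quasi-equilibrium approximation: binding is algebraic, with free fractions
given by the mass-balance quadratic

φ = (C − T − K_D + √((C − T − K_D)² + 4·K_D·C)) / (2C),

where C is the total concentration of the species of interest and T its
binding partner. Drug amounts follow a three-compartment oral model (transit
absorption with lag) in which every distribution and elimination rate
applies to the *free* drug only; plasma VAP-1 activity follows a power model
of free soluble target, `Act = SL · (φ_tVAP1 · sVAP1_c)^POW`. Covariates:
renal function (eGFR) acts on clearance through a near-switch sigmoid Emax
(Hill 10, EC50 77) and on relative bioavailability through a power law; sex
raises the VAP-1 pools 12.5% in females. Log-normal inter-individual
variability (full 3×3 covariance on CL, sVAP1_c, SL) and additive log-scale
residual error (phase-2 SD factor 1.88) complete the population model. All
fitted values ship in `src/vaptmdd/data/asp8232_parameters.yaml`.

Because the underlying clinical datasets are not public, the package
includes a first-class synthetic-data module that emulates the four studies'
designs and covariate distributions, and an estimation module (Laplace-
approximate marginal likelihood with empirical-Bayes etas, stepwise
covariate selection, CWRES outlier flagging) that is validated by parameter
recovery on those synthetic cohorts.

## Worked example

```python
from vaptmdd import (Subject, apply_covariates, daily_regimen,
                     default_parameters, secondary_params,
                     simulate_profile, steady_state_grid)

theta = default_parameters()
ip = apply_covariates(theta, Subject(sex="male", egfr=44.0))
regimen = daily_regimen(40.0, 52 * 7)           # 40 mg QD for 52 weeks
profile = simulate_profile(ip, regimen, 52 * 168.0, steady_state_grid(52))
print(secondary_params(profile, regimen))
```

prints

```
SecondaryPK(auc24_52w=2320.43..., cmax_52w=185.72..., tmax_52w=1.6,
            tss=0.857..., t_half_apparent=0.171...)
```

— at steady state the typical DKD patient (male, eGFR 44) on 40 mg daily
has a 24-h AUC of ≈2320 ng·h/mL, a peak of ≈186 ng/mL 1.6 h after dosing,
and reaches steady state in under a week. Running
`examples/typical_profile.py` sweeps doses and shows the TMDD nonlinearity:

```
  dose  AUC24 (ng*h/mL)  Cmax (ng/mL)  Tmax (h)  Tss (wk)  inhib (%)
   0.1             26.0          1.18       2.0     43.86       30.8
     1            106.3          6.39       1.5      8.57       79.6
    10            623.2         48.22       1.6      1.29       96.6
    30           1754.8        139.90       1.6      0.86       98.6
    40           2320.4        185.72       1.6      0.86       98.9
```

Dose-normalized exposure at 0.1 mg is ≈4-fold that at 40 mg, and time to
steady state stretches beyond 40 weeks — both signatures of saturable
target binding. The other scripts in `examples/` cover the population
dose–response (`dose_response.py`), the concentration–effect curve with its
≈2 ng/mL half-inhibition point (`concentration_effect.py`), and a full
generate-and-refit round trip (`fit_synthetic.py`). A thin CLI wraps the
same functionality (`vaptmdd simulate|cohort|fit|vpc|dose-response|curve`).

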