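# Methods

## Model

ASP8232 disposition is a three-compartment oral model whose distribution
and elimination fluxes act on free drug only. The state is the amount
vector (A1 depot, At transit, A2 central, A3 first peripheral, A4 second
peripheral), in nmol (molecular weight 444 g/mol converts doses and assay
concentrations):

    dA1/dt = −ka·A1
    dAt/dt =  ka·A1 − ka·At
    dA2/dt =  ka·At − φc·(k20+k23+k24)·A2 + φp1·k32·A3 + φp2·k42·A4
    dA3/dt =  φc·k23·A2 − φp1·k32·A3
    dA4/dt =  φc·k24·A2 − φp2·k42·A4

with k20 = CL/V2, k23 = Q/V2, k32 = Q/V3 (V3 = V2 fixed), k24 = Q2/V2,
k42 = Q2/V4, all apparent (…/F1). Each φ is the quasi-equilibrium free
fraction of drug in its compartment against that compartment's VAP-1 pool
(tVAP1_c = sVAP1_c·(1+f_mc) centrally; mVAP1_p1 = 52·sVAP1_c and
mVAP1_p2 = mVAP1_p1 peripherally), all sharing one K_D. Quasi-equilibrium
assumes binding is fast relative to disposition and that target turnover
and complex elimination are negligible; consequently total soluble target
is constant and the sVAP-1 concentration prediction is flat.

Observables (log scale): total plasma drug = free drug plus the
sVAP-1-bound share of the complex (weighted sVAP1_c/tVAP1_c, since the
assay sees plasma but not membrane-bound complex); total sVAP-1; VAP-1
activity = SL·(free sVAP-1)^POW. Inhibition is expressed against the
drug-free baseline SL·sVAP1_c^POW. Because SL cancels in the ratio, the
concentration–effect curve depends only on K_D, the pool sizes and POW.

Covariate submodels: CL_i = CL·(1 + 1.3·eGFR¹⁰/(77¹⁰ + eGFR¹⁰)) — an
effectively on/off switch at eGFR ≈ 77; F1 = (eGFR/44)^−0.257; female
sVAP1_c (+ all dependent pools) ×1.125. Random effects are exponential on
CL, sVAP1_c and SL with a full 3×3 covariance; residual error is additive
on the log scale per observation type, with the SD of phase-2 drug and
activity observations multiplied by 1.88.

**F1 reference (open design point).** The power law on bioavailability
needs a normalizing eGFR, which is not part of the published parameter
table. We normalize at eGFR 44 — the typical-subject/DKD-median value —
because with that convention the analytic steady-state identity
AUC_free = F1·Dose/CL, plus the bounded soluble-complex contribution,
reproduces the published secondary-PK table across 1–40 mg to within ~2%.
The value is exposed as `egfr_ref_f1` in the configuration.

**Units note.** The source tables label baseline VAP-1 activity in nM and
VAP-1 plasma concentration in pmol/mL/h; the activity model here is in
nM-equivalents throughout, consistent with the activity equation.

## Numerics

Simulation integrates the ODE with an embedded Dormand–Prince 5(4) pair at
rtol 1e-8 / atol 1e-10 nmol. The fitted rate constants span ~0.08–3.1 1/h
and the free-fraction nonlinearity is smooth, so the system is at most
mildly stiff and an explicit adaptive pair meets these tolerances; the
kernel is cross-checked against LSODA on the reference right-hand side in
the test suite. The kernel advances whole batches of subjects with a
shared adaptive step (error norm over the batch), which makes 1000-subject,
52-week population simulations take seconds on one core. Doses enter the
depot at their event time plus the absorption lag; troughs are sampled
immediately pre-dose; the free-fraction quadratic uses the conjugate root
form on the cancellation-prone branch and the analytic limit
K_D/(K_D + T) below 1e-12 nM total.

Steady-state metrics use the final dosing interval: AUC by trapezoid on a
0.1 h grid (validated once against an integrator-carried quadrature state,
<0.05% error), Cmax/Tmax from the same grid, time to steady state as the
first daily trough reaching 97% of the week-52 trough (hence a 1-day
resolution), and apparent half-life Tss/5 by definition. The 52-week
horizon is 364 days. Doses outside 0.1–200 mg warn rather than fail: the
model was calibrated on that range and target turnover, neglected here,
could matter beyond it.

## Synthetic data

The cohort generator emulates the study populations: sex ~ Bernoulli
(77.5% male for the DKD phase-2 study) and eGFR ~ truncated normal. The
DKD eGFR parameters (mean 44, SD 11.1, bounds [22.1, 71.5]) are derived
from the published median, 5th/95th percentiles and range assuming
normality. Datasets follow the NONMEM longitudinal convention
(ID/TIME/AMT/EVID/CMT/DV/MDV + covariates), DV on the log scale, with
preset observation schedules mirroring the phase-2 week grid and a rich
phase-1 day-1/day-14 grid. Drug observations below the 0.1 ng/mL assay
LLOQ are flagged but retained; estimation masks them by default (the
sources do not describe BLQ handling, and activity had no BLQ data).

What the generator does *not* emulate: dropout and dosing non-compliance,
assay drift and the placebo-arm activity fluctuations noted in the source
data, body-weight effects (carried as a column, no model effect — the
final model kept none), and the unexplained ~20% apparent inhibition
observed at very low concentrations (the model tends to 0% there by
design). Passing recovery tests therefore demonstrates internal
consistency of estimator and simulator under the stated model, not
robustness to these real-data features.

## Estimation

The marginal likelihood is approximated by Laplace's method at the MAP
(empirical-Bayes) etas, with the Gauss–Newton curvature J'Σ⁻¹J + Ω⁻¹
(J = eta-sensitivities of the log-scale predictions, by forward
differences with step 1e-4). MAP etas are solved per subject by damped
Gauss–Newton, warm-started across outer iterations, with final residuals
linearized through the last Jacobian. The outer problem (structural
parameters on the log scale, omega through its log-Cholesky factor,
residual variances on the log scale) is solved by L-BFGS-B under box
bounds; its finite-difference gradient evaluates a frozen-Jacobian
("envelope") version of the objective in which the eta-Jacobians are held
at the current iterate, so each gradient component costs a single batched
simulation — the Jacobians' own parameter dependence cancels to first
order between the base and perturbed evaluations. Fitting integrates at
rtol 1e-5 (max state error ~5e-6 against a 1e-10 reference). These are
the standard FOCE/Laplace-family approximations; agreement with any
specific implementation's OFV is not claimed — the estimator is validated
by parameter recovery on synthetic cohorts (see the test suite).

The standalone `map_etas` uses multistart (0 and ±0.5 per axis) L-BFGS
on the penalized deviance. CWRES are conditional residuals at the MAP
etas standardized by σ·√(1−h), where the leverage h = w·diag(J G⁻¹ J')
corrects the deflation caused by empirical-Bayes shrinkage; records with
|CWRES| strictly above 3 are flagged (and can be masked from refits
without deletion). Stepwise covariate selection screens candidates
univariately, adds forward while ΔOFV ≥ 6.63 (p < 0.01, χ² 1 df) and
retains on backward deletion only effects whose removal costs ≥ 10.8
(p < 0.001).

The recovery experiment in the acceptance tests uses the 12-week
on-treatment phase-2 design (observations through week 12): clearance,
target concentration, activity slope and power are well informed by
on-treatment data, and the shorter horizon keeps the 3-replicate,
120-subject experiment fast. K_D is held fixed when POW is estimated;
the two are strongly correlated (≈0.9 reported) and freeing both on
sparse designs is poorly identified — a configuration choice, not a
structural constraint.

## Known limitations

* No target turnover or complex elimination: extrapolation above ~200 mg
  (where less-than-proportional exposure was observed and excluded) is
  unreliable.
* The Laplace/Gauss–Newton OFV differs from other software's FOCE-I OFV
  by approximation details; ΔOFV-based decisions use the same statistic
  consistently, which is what the selection thresholds require.
* Tss has 1-day granularity by construction (daily troughs).
* Information-matrix standard errors are not computed; uncertainty
  quantification beyond eta shrinkage is out of scope.
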