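# Final ASP8232 population PK-PD TMDD model: point estimates and variance
# components.  Units: rates 1/h, lag h, clearances L/h (apparent, /F1),
# volumes L (apparent, /F1), concentrations nM, EC50 in mL/min/1.73m2.
# V3_factor, f_mVAP1p2 and hill_egfr_cl are fixed structural values.
# egfr_ref_f1 normalizes the eGFR power on relative bioavailability so that
# F1 = 1 at the reference renal function (ALBUM-median, typical subject).
theta:
  ka: 3.12
  LAG: 0.31
  CL: 17.6
  V2: 210.0
  Q: 37.6
  V3_factor: 1.0
  Q2: 80.5
  V4: 26.7
  KD: 0.929
  sVAP1c: 5.52
  f_mVAP1c: 2.13
  f_mVAP1p1: 52.0
  f_mVAP1p2: 1.0
  SL: 851.0
  POW: 0.851
  emax_egfr_cl: 1.3
  ec50_egfr_cl: 77.0
  hill_egfr_cl: 10.0
  pow_egfr_f1: -0.257
  sex_vap1: 0.125
  egfr_ref_f1: 44.0
omega_sigma:
  # Covariance of (eta_CL, eta_sVAP1c, eta_SL); full block.
  omega:
    - [0.128, 0.0213, -0.0301]
    - [0.0213, 0.0735, -0.0222]
    - [-0.0301, -0.0222, 0.0574]
  # Additive log-scale residual variances.
  sigma2_pk: 0.115
  sigma2_vap1conc: 0.0351
  sigma2_vap1act: 0.0696
  # Multiplier on the residual SD of phase-2 drug and activity observations.
  phase2_factor: 1.88
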