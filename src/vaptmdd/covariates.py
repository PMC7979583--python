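"""Covariate submodels and individual-parameter resolution.

The final model carries three covariate effects:

* eGFR on CL via a sigmoid Emax ("switch") relationship with Hill power
  fixed at 10: ``CL_i = CL * (1 + Emax * eGFR^10 / (EC50^10 + eGFR^10))``,
  so clearance rises steeply once renal function exceeds EC50 = 77.
* eGFR on relative bioavailability F1 via a power relationship
  ``F1 = (eGFR / eGFR_ref)^pow`` (negative power: exposure rises as renal
  function falls).
* Sex on the VAP-1 concentrations: all target pools are parameterized as
  multiples of sVAP1c, which is 12.5% higher for females.

Random effects enter exponentially (log-normal) on CL, sVAP1c and SL.

For covariate *selection* experiments, :class:`CovariateEffect` expresses a
candidate relationship (power / sigmoid-Emax / categorical shift) on any of
the IIV-carrying parameters or V2, applied on top of a base model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import IndividualParameters, ModelParameters, Subject

__all__ = ["apply_covariates", "CovariateEffect", "apply_covariate_effects"]


def apply_covariates(theta: ModelParameters, subject: Subject) -> IndividualParameters:
    """Resolve the final model's individual parameters for one subject."""
    if subject.egfr <= 0:
        raise ValueError("egfr must be strictly positive")
    e, h = subject.egfr, theta.hill_egfr_cl
    hill = e**h / (theta.ec50_egfr_cl**h + e**h)
    cl_i = theta.CL * (1.0 + theta.emax_egfr_cl * hill) * np.exp(subject.eta_cl)
    f1_rel = (e / theta.egfr_ref_f1) ** theta.pow_egfr_f1
    sex_mult = 1.0 + theta.sex_vap1 * (subject.sex == "female")
    svap1_i = theta.sVAP1c * sex_mult * np.exp(subject.eta_svap1)
    sl_i = theta.SL * np.exp(subject.eta_sl)
    return IndividualParameters(
        ka=theta.ka,
        LAG=theta.LAG,
        CL=cl_i,
        V2=theta.V2,
        V3=theta.V3,
        V4=theta.V4,
        Q=theta.Q,
        Q2=theta.Q2,
        KD=theta.KD,
        sVAP1c=svap1_i,
        tVAP1c=svap1_i * (1.0 + theta.f_mVAP1c),
        mVAP1p1=svap1_i * theta.f_mVAP1p1,
        mVAP1p2=svap1_i * theta.f_mVAP1p1 * theta.f_mVAP1p2,
        SL=sl_i,
        POW=theta.POW,
        f1_rel=f1_rel,
    )


@dataclass(frozen=True)
class CovariateEffect:
    """One candidate covariate relationship for model building.

    parameter: one of {"CL", "sVAP1c", "SL", "V2"} (IIV-carrying or V2).
    covariate: subject attribute, {"egfr", "weight", "sex"}.
    form: "power" (one coefficient, centered at ``reference``),
          "sigmoid_emax" (Emax and EC50, Hill fixed at ``hill``), or
          "categorical" (one fractional shift for females).
    """

    parameter: str
    covariate: str
    form: str
    reference: float = 1.0
    hill: float = 10.0

    _PARAMS = ("CL", "sVAP1c", "SL", "V2")

    def __post_init__(self):
        if self.parameter not in self._PARAMS:
            raise ValueError(
                f"covariate effects allowed only on {self._PARAMS}, got {self.parameter!r}"
            )
        if self.form not in ("power", "sigmoid_emax", "categorical"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "categorical" and self.covariate != "sex":
            raise ValueError("categorical form is defined for the sex covariate")

    @property
    def n_coef(self) -> int:
        return 2 if self.form == "sigmoid_emax" else 1

    def multiplier(self, subject: Subject, coef: np.ndarray) -> float:
        """Parameter multiplier for ``subject`` given coefficient(s)."""
        if self.form == "categorical":
            return max(1.0 + coef[0] * (subject.sex == "female"), 1e-6)
        x = getattr(subject, self.covariate)
        if self.form == "power":
            return (x / self.reference) ** coef[0]
        emax, ec50 = coef
        hl = x**self.hill / (abs(ec50) ** self.hill + x**self.hill)
        return max(1.0 + emax * hl, 1e-6)


def apply_covariate_effects(
    theta: ModelParameters,
    subject: Subject,
    effects: list[CovariateEffect],
    coefs: list[np.ndarray],
) -> IndividualParameters:
    """Resolve individual parameters for a base model plus candidate effects.

    The base model's own covariate fields still apply (set them to zero in
    ``theta`` for a covariate-free base).  Effects multiply the targeted
    structural parameter before the random effect is applied.
    """
    mult = {"CL": 1.0, "sVAP1c": 1.0, "SL": 1.0, "V2": 1.0}
    for eff, c in zip(effects, coefs):
        mult[eff.parameter] *= eff.multiplier(subject, np.atleast_1d(c))
    adj = theta.replace(
        CL=theta.CL * mult["CL"],
        sVAP1c=theta.sVAP1c * mult["sVAP1c"],
        SL=theta.SL * mult["SL"],
        V2=theta.V2 * mult["V2"],
    )
    return apply_covariates(adj, subject)
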