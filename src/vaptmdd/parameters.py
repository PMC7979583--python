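"""Model parameters, subjects, and variance components.

The fixed-effect estimates of the final ASP8232 population PK-PD model ship
as a packaged YAML file (``data/asp8232_parameters.yaml``) and load through
:func:`default_parameters` / :func:`default_omega_sigma`.  Apparent PK
parameters (CL/F1, V2/F1, ...) absorb the relative oral bioavailability F1;
target concentrations are molar (nM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "OmegaSigma",
    "Subject",
    "IndividualParameters",
    "default_parameters",
    "default_omega_sigma",
    "load_config",
    "save_config",
]

#: Order of the random-effect axes throughout the package.
ETA_NAMES = ("CL", "sVAP1c", "SL")


@dataclass
class ModelParameters:
    """Population (typical-value) parameters of the TMDD model.

    Units: rates 1/h, lag h, clearances L/h, volumes L, concentrations nM.
    ``V3_factor``, ``f_mVAP1p2`` and ``hill_egfr_cl`` are structurally fixed
    in the final model (V3 = V2, mVAP1_p2 = mVAP1_p1, Hill power 10).
    """

    ka: float = 3.12
    LAG: float = 0.31
    CL: float = 17.6
    V2: float = 210.0
    Q: float = 37.6
    V3_factor: float = 1.0
    Q2: float = 80.5
    V4: float = 26.7
    KD: float = 0.929
    sVAP1c: float = 5.52
    f_mVAP1c: float = 2.13
    f_mVAP1p1: float = 52.0
    f_mVAP1p2: float = 1.0
    SL: float = 851.0
    POW: float = 0.851
    emax_egfr_cl: float = 1.3
    ec50_egfr_cl: float = 77.0
    hill_egfr_cl: float = 10.0
    pow_egfr_f1: float = -0.257
    sex_vap1: float = 0.125
    egfr_ref_f1: float = 44.0

    def __post_init__(self):
        for name in ("ka", "CL", "V2", "Q", "Q2", "V4", "KD", "sVAP1c", "SL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.LAG < 0:
            raise ValueError("LAG must be non-negative")
        if not 0.0 < self.POW < 2.0:
            raise ValueError("POW must lie in (0, 2)")
        if self.egfr_ref_f1 <= 0:
            raise ValueError("egfr_ref_f1 must be strictly positive")

    @property
    def V3(self) -> float:
        return self.V3_factor * self.V2

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class OmegaSigma:
    """Random-effect covariance and residual variances (log scale).

    ``omega`` is the 3x3 covariance of (eta_CL, eta_sVAP1c, eta_SL); the
    residual variances are additive on the log scale, with the residual SD
    of phase-2 drug and activity observations multiplied by
    ``phase2_factor``.
    """

    omega: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.128, 0.0213, -0.0301],
                [0.0213, 0.0735, -0.0222],
                [-0.0301, -0.0222, 0.0574],
            ]
        )
    )
    sigma2_pk: float = 0.115
    sigma2_vap1conc: float = 0.0351
    sigma2_vap1act: float = 0.0696
    phase2_factor: float = 1.88

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (3, 3):
            raise ValueError("omega must be 3x3 (CL, sVAP1c, SL order)")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh(self.omega)) < -1e-12:
            raise ValueError("omega must be positive semi-definite")
        for name in ("sigma2_pk", "sigma2_vap1conc", "sigma2_vap1act", "phase2_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def sigma2_for(self, obs_type: str, phase2: bool = False) -> float:
        """Residual variance for an observation type, phase-scaled.

        The phase-2 factor multiplies the residual *SD* of drug and
        activity observations, hence the variance by its square.
        """
        base = {
            "drug": self.sigma2_pk,
            "svap1": self.sigma2_vap1conc,
            "activity": self.sigma2_vap1act,
        }[obs_type]
        if phase2 and obs_type in ("drug", "activity"):
            return base * self.phase2_factor**2
        return base

    def to_dict(self) -> dict:
        return {
            "omega": [[float(x) for x in row] for row in self.omega],
            "sigma2_pk": float(self.sigma2_pk),
            "sigma2_vap1conc": float(self.sigma2_vap1conc),
            "sigma2_vap1act": float(self.sigma2_vap1act),
            "phase2_factor": float(self.phase2_factor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OmegaSigma":
        d = dict(d)
        d["omega"] = np.asarray(d["omega"], dtype=float)
        return cls(**d)


@dataclass
class Subject:
    """One virtual individual: covariates plus random effects.

    ``egfr`` is the baseline CKD-EPI estimated glomerular filtration rate in
    mL/min/1.73m2; etas are log-scale random effects in (CL, sVAP1c, SL)
    order.
    """

    id: int | str = 0
    sex: str = "male"
    egfr: float = 44.0
    weight: float = 85.0
    study_phase: str = "phase2"
    eta_cl: float = 0.0
    eta_svap1: float = 0.0
    eta_sl: float = 0.0

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.study_phase not in ("phase1", "phase2"):
            raise ValueError("study_phase must be 'phase1' or 'phase2'")
        if self.egfr <= 0:
            raise ValueError("egfr must be strictly positive")
        for name in ("eta_cl", "eta_svap1", "eta_sl"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def etas(self) -> np.ndarray:
        return np.array([self.eta_cl, self.eta_svap1, self.eta_sl])


@dataclass
class IndividualParameters:
    """Parameters after covariate application and random effects.

    Same structural fields as :class:`ModelParameters` plus the relative
    bioavailability multiplier ``f1_rel`` (applied to each dose) and the
    resolved target concentrations.  ``tVAP1c = sVAP1c * (1 + f_mVAP1c)``
    is the total (soluble + membrane-accessible) central target pool.
    """

    ka: float
    LAG: float
    CL: float
    V2: float
    V3: float
    V4: float
    Q: float
    Q2: float
    KD: float
    sVAP1c: float
    tVAP1c: float
    mVAP1p1: float
    mVAP1p2: float
    SL: float
    POW: float
    f1_rel: float

    def __post_init__(self):
        if self.f1_rel <= 0:
            raise ValueError("f1_rel must be strictly positive")

    # Derived micro rate constants (never stored).
    @property
    def k20(self) -> float:
        return self.CL / self.V2

    @property
    def k23(self) -> float:
        return self.Q / self.V2

    @property
    def k32(self) -> float:
        return self.Q / self.V3

    @property
    def k24(self) -> float:
        return self.Q2 / self.V2

    @property
    def k42(self) -> float:
        return self.Q2 / self.V4

    @property
    def baseline_activity(self) -> float:
        """Drug-free VAP-1 plasma activity, SL * sVAP1c**POW (nM)."""
        return self.SL * self.sVAP1c**self.POW


def _data_path(name: str):
    return resources.files("vaptmdd").joinpath("data").joinpath(name)


def default_parameters() -> ModelParameters:
    """Final-model fixed-effect estimates from the packaged configuration."""
    cfg = yaml.safe_load(_data_path("asp8232_parameters.yaml").read_text())
    return ModelParameters.from_dict(cfg["theta"])


def default_omega_sigma() -> OmegaSigma:
    """Final-model variance components from the packaged configuration."""
    cfg = yaml.safe_load(_data_path("asp8232_parameters.yaml").read_text())
    return OmegaSigma.from_dict(cfg["omega_sigma"])


def load_config(path) -> tuple[ModelParameters, OmegaSigma]:
    """Load a ``{theta: ..., omega_sigma: ...}`` YAML configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return (
        ModelParameters.from_dict(cfg["theta"]),
        OmegaSigma.from_dict(cfg["omega_sigma"]),
    )


def save_config(path, theta: ModelParameters, omega_sigma: OmegaSigma) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"theta": theta.to_dict(), "omega_sigma": omega_sigma.to_dict()},
            fh,
            sort_keys=False,
        )
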