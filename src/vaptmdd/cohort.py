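"""Synthetic cohorts, sampling designs, and NONMEM-style datasets.

No clinical data are available for this model, so every downstream stage
(estimation, diagnostics, VPC) runs on synthetic datasets generated here.
Virtual subjects emulate the study populations: sex is Bernoulli with the
study's male fraction and eGFR is drawn from a truncated normal matched to
the study's printed distribution.  Observation datasets follow the NONMEM
longitudinal convention (ID/TIME/AMT/EVID/CMT/DV/MDV plus covariates), with
DV the log-scale observation and additive log-scale residual noise whose SD
is inflated by the phase-2 factor for phase-2 drug and activity records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import apply_covariates
from .parameters import ModelParameters, OmegaSigma, Subject
from .regimen import Regimen, build_regimen
from .simulate import observations_from_states, simulate_states
from .units import ng_per_mL_to_nM

__all__ = [
    "PopulationSpec",
    "SamplingDesign",
    "ALBUM_POPULATION",
    "DESIGN_PRESETS",
    "sample_covariates",
    "sample_etas",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: Observation-type codes in the CMT column (1 is the dose/depot record).
CMT_DOSE, CMT_DRUG, CMT_SVAP1, CMT_ACTIVITY = 1, 2, 3, 4
CMT_TO_TYPE = {CMT_DRUG: "drug", CMT_SVAP1: "svap1", CMT_ACTIVITY: "activity"}
TYPE_TO_CMT = {v: k for k, v in CMT_TO_TYPE.items()}

#: Assay lower limit of quantification for plasma drug concentration.
LLOQ_DRUG_NG_ML = 0.1

#: Fixed column order emitted by :func:`write_dataset`.
DATASET_COLUMNS = [
    "ID", "TIME", "AMT", "EVID", "CMT", "DV", "MDV",
    "LLOQFLAG", "SEX", "EGFR", "WEIGHT", "PHASE",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Covariate distribution of a virtual study population."""

    n: int
    male_fraction: float
    egfr_mean: float
    egfr_sd: float
    egfr_bounds: tuple[float, float]
    phase: str = "phase2"
    weight_mean: float = 85.0
    weight_sd: float = 15.0

    def __post_init__(self):
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.egfr_sd <= 0:
            raise ValueError("egfr_sd must be strictly positive")
        lo, hi = self.egfr_bounds
        if not 0 < lo < hi:
            raise ValueError("egfr_bounds must be positive and ordered")


# DKD population of the 12-week phase-2 trial: 77.5% male; eGFR matched to
# the printed median 44 and 5th/95th percentiles (26.9 / 63.4) assuming
# normality (SD = (63.4 - 26.9) / (2 * 1.645) ~ 11.1), truncated at the
# printed min/max.
ALBUM_POPULATION = PopulationSpec(
    n=120,
    male_fraction=0.775,
    egfr_mean=44.0,
    egfr_sd=11.1,
    egfr_bounds=(22.1, 71.5),
    phase="phase2",
)


@dataclass(frozen=True)
class SamplingDesign:
    """Observation schedule: (time h, observation type) plus a regimen."""

    schedule: tuple[tuple[float, str], ...]
    regimen: str | Regimen = "ALBUM"
    label: str = ""

    def __post_init__(self):
        for t, typ in self.schedule:
            if t < 0:
                raise ValueError("sampling times must be non-negative")
            if typ not in TYPE_TO_CMT:
                raise ValueError(f"unknown observation type {typ!r}")

    @property
    def horizon(self) -> float:
        return max((t for t, _ in self.schedule), default=0.0)


def _week_schedule() -> tuple[tuple[float, str], ...]:
    # Scheduled visit grid of the 12-week phase-2 study: drug concentration
    # from week 2 on; target concentration and activity from baseline on.
    drug_weeks = (2, 4, 8, 12, 16, 24, 36)
    pd_weeks = (0, 2, 4, 6, 8, 12, 16, 24, 36)
    sched = [(168.0 * w, "drug") for w in drug_weeks]
    sched += [(168.0 * w, "svap1") for w in pd_weeks]
    sched += [(168.0 * w, "activity") for w in pd_weeks]
    return tuple(sched)


def _treatment_schedule() -> tuple[tuple[float, str], ...]:
    # On-treatment subset (through week 12) of the phase-2 visit grid.
    return tuple((t, typ) for t, typ in _week_schedule() if t <= 168.0 * 12)


def _phase1_schedule() -> tuple[tuple[float, str], ...]:
    # Rich day-1 / day-14 sampling of a multiple-dose phase-1 arm.
    rich = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    sched = [(t, "drug") for t in rich]
    sched += [(13 * 24.0 + t, "drug") for t in rich]
    sched += [(t, "activity") for t in (0.0, 1.0, 4.0, 12.0, 24.0)]
    sched += [(13 * 24.0 + t, "activity") for t in (1.0, 4.0, 12.0, 24.0)]
    return tuple(sorted(sched))


DESIGN_PRESETS: dict[str, SamplingDesign] = {
    "ALBUM": SamplingDesign(_week_schedule(), "ALBUM", "ALBUM week grid"),
    "ALBUM-treatment": SamplingDesign(
        _treatment_schedule(), "ALBUM", "ALBUM on-treatment weeks 0-12"
    ),
    "phase1-rich": SamplingDesign(
        _phase1_schedule(), "0002-part2", "rich day-1/day-14 phase-1 grid"
    ),
}


def sample_covariates(spec: PopulationSpec, seed=None) -> list[Subject]:
    """Draw a virtual cohort from a population specification."""
    if spec.n <= 0:
        return []
    rng = np.random.default_rng(seed)
    lo, hi = spec.egfr_bounds
    a, b = (lo - spec.egfr_mean) / spec.egfr_sd, (hi - spec.egfr_mean) / spec.egfr_sd
    egfr = stats.truncnorm.rvs(
        a, b, loc=spec.egfr_mean, scale=spec.egfr_sd, size=spec.n, random_state=rng
    )
    male = rng.random(spec.n) < spec.male_fraction
    weight = np.maximum(
        rng.normal(spec.weight_mean, spec.weight_sd, size=spec.n), 35.0
    )
    return [
        Subject(
            id=i + 1,
            sex="male" if male[i] else "female",
            egfr=float(egfr[i]),
            weight=float(weight[i]),
            study_phase=spec.phase,
        )
        for i in range(spec.n)
    ]


def sample_etas(omega: np.ndarray, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` zero-mean multivariate-normal eta triplets."""
    omega = np.asarray(omega, dtype=float)
    if np.min(np.linalg.eigvalsh((omega + omega.T) / 2)) < -1e-12:
        raise ValueError("omega must be positive semi-definite")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(omega.shape[0]), omega, size=n)


def attach_etas(cohort: list[Subject], etas: np.ndarray) -> list[Subject]:
    return [
        replace(s, eta_cl=float(e[0]), eta_svap1=float(e[1]), eta_sl=float(e[2]))
        for s, e in zip(cohort, etas)
    ]


def generate_dataset(
    cohort: list[Subject],
    design: SamplingDesign | str,
    theta: ModelParameters,
    omega_sigma: OmegaSigma,
    seed=None,
    sample_iiv: bool = True,
    lloq_ng_ml: float = LLOQ_DRUG_NG_ML,
) -> pd.DataFrame:
    """Simulate a noisy NONMEM-style longitudinal dataset.

    Each subject is simulated noiselessly at the design's schedule, then
    independent N(0, sigma^2) noise is added to each log-scale observation;
    for phase-2 subjects the residual SD of drug and activity observations
    is multiplied by the phase-2 factor.  Drug observations below the assay
    LLOQ are flagged (LLOQFLAG = 1) but keep their simulated value.
    Returns rows time-sorted within subject; dose rows have EVID = MDV = 1.
    """
    if isinstance(design, str):
        design = DESIGN_PRESETS[design]
    regimen = build_regimen(design.regimen)
    rng = np.random.default_rng(seed)
    if sample_iiv:
        cohort = attach_etas(cohort, sample_etas(omega_sigma.omega, len(cohort), rng))
    params_list = [apply_covariates(theta, s) for s in cohort]

    obs = sorted(design.schedule)
    obs_times = np.array([t for t, _ in obs])
    grid = np.unique(obs_times)
    states = simulate_states(params_list, regimen, grid)
    conc_ng, act = observations_from_states(states, params_list)
    gidx = np.searchsorted(grid, obs_times)

    lloq_log_nM = np.log(ng_per_mL_to_nM(lloq_ng_ml))
    frames = []
    for i, (subj, ip) in enumerate(zip(cohort, params_list)):
        phase2 = subj.study_phase == "phase2"
        rows = []
        for t, amt in regimen.events:
            rows.append((t, amt, 1, CMT_DOSE, np.nan, 1, 0))
        for (t, typ), g in zip(obs, gidx):
            if typ == "drug":
                pred = np.log(ng_per_mL_to_nM(conc_ng[g, i])) if conc_ng[g, i] > 0 else -np.inf
            elif typ == "svap1":
                pred = np.log(ip.sVAP1c)
            else:
                pred = np.log(act[g, i])
            sd = np.sqrt(omega_sigma.sigma2_for(typ, phase2))
            dv = pred + rng.normal(0.0, sd) if np.isfinite(pred) else -np.inf
            flag = int(typ == "drug" and dv < lloq_log_nM)
            rows.append((t, 0.0, 0, TYPE_TO_CMT[typ], dv, 0, flag))
        df = pd.DataFrame(
            rows, columns=["TIME", "AMT", "EVID", "CMT", "DV", "MDV", "LLOQFLAG"]
        )
        df.insert(0, "ID", subj.id)
        df["SEX"] = 0 if subj.sex == "male" else 1
        df["EGFR"] = subj.egfr
        df["WEIGHT"] = subj.weight
        df["PHASE"] = 2 if phase2 else 1
        df = df.sort_values(["TIME", "EVID"], kind="stable")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[DATASET_COLUMNS]


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset as CSV in the documented fixed column order."""
    df[DATASET_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV; tolerates column reordering."""
    df = pd.read_csv(path, comment="#")
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    return df[DATASET_COLUMNS]
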