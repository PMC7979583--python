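"""Concentration-time simulation and secondary PK/PD metrics.

Doses enter the depot as ``f1_rel * dose_nmol`` at the event time plus the
absorption lag; the state is integrated piecewise between events and the
observation equations are evaluated on the requested grid.  Steady-state
metrics follow the usual once-daily conventions: the 24-h AUC, Cmax and
Tmax are taken over the final dosing interval, the trough is the
concentration sampled immediately before each daily dose, time to steady
state is the first daily trough reaching 97% of the end-of-treatment
trough, and the apparent half-life is Tss/5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .covariates import apply_covariates
from .model import pack_individual
from .parameters import IndividualParameters, ModelParameters, Subject
from .regimen import Regimen, build_regimen, daily_regimen
from .units import mg_to_nmol, nM_to_ng_per_mL

__all__ = [
    "ProfileResult",
    "SecondaryPK",
    "simulate_profile",
    "simulate_states",
    "steady_state_grid",
    "secondary_params",
    "average_inhibition_24h",
    "simulate_population",
    "summarize_population",
    "dose_normalized_auc",
]

TSS_FRACTION = 0.97
HOURS_PER_WEEK = 168.0


def phi_free(c_total, partner_total, kd):
    """Vectorized quasi-equilibrium free fraction (see :mod:`vaptmdd.binding`)."""
    c = np.asarray(c_total, dtype=float)
    t = np.broadcast_to(np.asarray(partner_total, dtype=float), c.shape)
    b = c - t - kd
    s = np.sqrt(b * b + 4.0 * kd * c)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(b >= 0.0, (b + s) / (2.0 * np.maximum(c, 1e-300)), 2.0 * kd / (s - b))
    r = np.where(c < 1e-12, kd / (kd + t), r)
    return np.minimum(r, 1.0)


@dataclass
class ProfileResult:
    """Simulated time profile for one subject.

    conc_drug_total is the assay-visible total ASP8232 plasma concentration
    in ng/mL; conc_svap1 and activity are in nM; inhibition is percent of
    the subject's drug-free baseline activity.
    """

    times: np.ndarray
    conc_drug_total: np.ndarray
    conc_svap1: np.ndarray
    activity: np.ndarray
    inhibition: np.ndarray
    baseline_activity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "conc_drug_ng_mL": self.conc_drug_total,
                "svap1_nM": self.conc_svap1,
                "activity_nM": self.activity,
                "inhibition_pct": self.inhibition,
            }
        )


@dataclass
class SecondaryPK:
    """Steady-state exposure metrics over the final once-daily interval."""

    auc24_52w: float  # ng*h/mL
    cmax_52w: float  # ng/mL
    tmax_52w: float  # h after the final dose
    tss: float  # weeks
    t_half_apparent: float  # weeks, = tss / 5 by definition


def simulate_states(
    params_list: list[IndividualParameters],
    regimen: Regimen,
    out_times: np.ndarray,
    rtol: float = _kernel.RTOL_SIM,
    atol: float = _kernel.ATOL_SIM,
) -> np.ndarray:
    """Integrate a batch of subjects over a shared regimen.

    All subjects share dose times and nominal amounts; each subject's doses
    are scaled by its own relative bioavailability.  Returns amounts with
    shape (n_times, n_subjects, 5).
    """
    p = np.array([pack_individual(ip) for ip in params_list])
    lag = params_list[0].LAG
    if any(ip.LAG != lag for ip in params_list):
        raise ValueError("batch simulation requires a shared LAG")
    out_times = np.asarray(out_times, dtype=float)
    dose_nmol = np.array([mg_to_nmol(a) for a in regimen.doses_mg], dtype=float)
    bp_t, bp_out, bp_dose = _kernel.build_breakpoints(regimen.times, lag, out_times)
    out = np.zeros((out_times.size, p.shape[0], 5))
    status = _kernel.integrate_regimen(p, bp_t, bp_out, bp_dose, dose_nmol, out, rtol, atol)
    if status != 0:
        raise RuntimeError(
            f"ODE integration failed (step-size underflow) for regimen "
            f"{regimen.label!r} over [0, {out_times[-1] if out_times.size else 0}] h"
        )
    return out


def observations_from_states(states: np.ndarray, params_list: list[IndividualParameters]):
    """Measured drug conc (ng/mL), activity (nM) for (n_times, n, 5) states."""
    v2 = np.array([ip.V2 for ip in params_list])
    tv = np.array([ip.tVAP1c for ip in params_list])
    sv = np.array([ip.sVAP1c for ip in params_list])
    kd = np.array([ip.KD for ip in params_list])
    sl = np.array([ip.SL for ip in params_list])
    pw = np.array([ip.POW for ip in params_list])
    c2 = states[:, :, 2] / v2
    phic = phi_free(c2, tv[None, :], kd[None, :])
    # Soluble share of the complex; zero-target subjects have no complex.
    w = np.divide(sv, tv, out=np.zeros_like(sv), where=tv > 0)
    meas_nM = phic * c2 + (1.0 - phic) * c2 * w
    phit = phi_free(np.broadcast_to(tv, c2.shape), c2, kd[None, :])
    activity = sl * (phit * sv) ** pw
    return nM_to_ng_per_mL(meas_nM), activity


def simulate_profile(
    params: IndividualParameters,
    regimen,
    horizon: float,
    grid: np.ndarray | None = None,
    rtol: float = _kernel.RTOL_SIM,
    atol: float = _kernel.ATOL_SIM,
) -> ProfileResult:
    """Simulate one subject's profile over ``[0, horizon]`` hours."""
    regimen = build_regimen(regimen)
    if regimen.events and regimen.end_time > horizon:
        raise ValueError("horizon must cover the regimen")
    if grid is None:
        grid = np.arange(0.0, horizon + 1e-9, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid[0] < 0 or grid[-1] > horizon + 1e-9):
        raise ValueError("grid must lie within [0, horizon]")
    states = simulate_states([params], regimen, grid, rtol, atol)
    conc, act = observations_from_states(states, [params])
    base = params.baseline_activity
    return ProfileResult(
        times=grid,
        conc_drug_total=conc[:, 0],
        conc_svap1=np.full(grid.size, params.sVAP1c),
        activity=act[:, 0],
        inhibition=100.0 * (1.0 - act[:, 0] / base),
        baseline_activity=base,
    )


def steady_state_grid(weeks: int = 52, dense_step: float = 0.1) -> np.ndarray:
    """Output grid with daily troughs plus a dense final dosing interval."""
    days = int(weeks) * 7
    troughs = 24.0 * np.arange(1, days + 1)
    final = np.arange(24.0 * (days - 1), 24.0 * days + 1e-9, dense_step)
    return np.unique(np.concatenate([[0.0], troughs, final]))


def secondary_params(
    profile: ProfileResult, regimen: Regimen, tss_fraction: float = TSS_FRACTION
) -> SecondaryPK:
    """Steady-state secondary PK metrics from a once-daily profile."""
    if not regimen.events:
        raise ValueError("regimen has no doses")
    t_last = regimen.end_time
    t_end = t_last + 24.0
    t, c = profile.times, profile.conc_drug_total
    if t[-1] < t_end - 1e-6:
        raise ValueError("profile must span the full final dosing interval")
    sel = (t >= t_last - 1e-9) & (t <= t_end + 1e-9)
    tf, cf = t[sel], c[sel]
    if tf.size < 3 or np.max(np.diff(tf)) > 0.1 + 1e-9:
        raise ValueError("final-interval grid must be dense (<= 0.1 h step)")
    auc = np.trapezoid(cf, tf)
    imax = int(np.argmax(cf))
    cmax, tmax = float(cf[imax]), float(tf[imax] - t_last)
    # Daily pre-dose troughs: profile values at the dose times (plus the
    # end-of-treatment trough at t_last + 24).
    trough_times = np.array([tt for tt in regimen.times if tt > 0] + [t_end])
    idx = np.searchsorted(t, trough_times - 1e-6)
    if np.any(idx >= t.size) or np.any(np.abs(t[idx] - trough_times) > 1e-6):
        raise ValueError("profile grid must include each daily trough time")
    troughs = c[idx]
    ref = troughs[-1]
    reached = np.nonzero(troughs >= tss_fraction * ref)[0]
    tss_weeks = trough_times[reached[0]] / HOURS_PER_WEEK
    return SecondaryPK(
        auc24_52w=float(auc),
        cmax_52w=cmax,
        tmax_52w=tmax,
        tss=float(tss_weeks),
        t_half_apparent=float(tss_weeks) / 5.0,
    )


def average_inhibition_24h(profile: ProfileResult, window=None) -> float:
    """Time-averaged inhibition (%) over a window (default: final 24 h)."""
    t = profile.times
    if window is None:
        window = (t[-1] - 24.0, t[-1])
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must be non-empty")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("window must lie inside the profile")
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if np.count_nonzero(sel) < 2:
        raise ValueError("window contains too few grid points")
    return float(np.trapezoid(profile.inhibition[sel], t[sel]) / (t[sel][-1] - t[sel][0]))


def simulate_population(
    theta: ModelParameters,
    omega: np.ndarray | None,
    cohort: list[Subject],
    dose_mg: float,
    weeks: int = 52,
    seed=None,
    rtol: float = _kernel.RTOL_SIM,
    atol: float = _kernel.ATOL_SIM,
) -> pd.DataFrame:
    """Population simulation of steady-state exposure and inhibition.

    Samples per-subject random effects from the full ``omega`` block (pass
    ``None`` to use the etas already on the subjects), applies covariates,
    simulates ``dose_mg`` once daily for ``weeks`` weeks, and returns one
    row per subject with the secondary PK metrics and the time-averaged
    VAP-1 inhibition over the final 24 h.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if omega is not None:
        omega = np.asarray(omega, dtype=float)
        if np.min(np.linalg.eigvalsh((omega + omega.T) / 2)) < -1e-12:
            raise ValueError("omega must be positive semi-definite")
        rng = np.random.default_rng(seed)
        etas = rng.multivariate_normal(np.zeros(3), omega, size=len(cohort))
        from dataclasses import replace

        cohort = [
            replace(s, eta_cl=e[0], eta_svap1=e[1], eta_sl=e[2])
            for s, e in zip(cohort, etas)
        ]
    params_list = [apply_covariates(theta, s) for s in cohort]
    regimen = daily_regimen(dose_mg, int(weeks) * 7)
    grid = steady_state_grid(weeks)
    states = simulate_states(params_list, regimen, grid, rtol, atol)
    conc, act = observations_from_states(states, params_list)

    t_last = regimen.end_time
    sel = (grid >= t_last - 1e-9) & (grid <= t_last + 24.0 + 1e-9)
    tf = grid[sel]
    trough_times = np.array([tt for tt in regimen.times if tt > 0] + [t_last + 24.0])
    tr_idx = np.searchsorted(grid, trough_times - 1e-6)

    rows = []
    for i, (subj, ip) in enumerate(zip(cohort, params_list)):
        cf = conc[sel, i]
        auc = float(np.trapezoid(cf, tf))
        imax = int(np.argmax(cf))
        troughs = conc[tr_idx, i]
        reached = np.nonzero(troughs >= TSS_FRACTION * troughs[-1])[0]
        tss = trough_times[reached[0]] / HOURS_PER_WEEK
        inh = 100.0 * (1.0 - act[sel, i] / ip.baseline_activity)
        avg_inh = float(np.trapezoid(inh, tf) / (tf[-1] - tf[0]))
        rows.append(
            {
                "id": subj.id,
                "sex": subj.sex,
                "egfr": subj.egfr,
                "dose_mg": dose_mg,
                "auc24": auc,
                "cmax": float(cf[imax]),
                "tmax": float(tf[imax] - t_last),
                "tss_weeks": float(tss),
                "t_half_weeks": float(tss) / 5.0,
                "avg_inhibition_24h": avg_inh,
            }
        )
    return pd.DataFrame(rows)


def summarize_population(metrics: pd.DataFrame) -> pd.DataFrame:
    """5th/50th/95th percentiles of each numeric population metric."""
    num = metrics.select_dtypes("number").drop(columns=["id"], errors="ignore")
    return num.quantile([0.05, 0.5, 0.95])


def dose_normalized_auc(metrics_by_dose: dict[float, pd.DataFrame], reference: float = 40.0):
    """Dose-normalized exposure, ``reference * AUC / dose`` per subject.

    Returns a long table (dose, id, auc24, dnauc) plus a per-dose
    percentile summary of the normalized exposure.
    """
    if any(d <= 0 for d in metrics_by_dose):
        raise ValueError("doses must be strictly positive")
    if reference not in metrics_by_dose:
        raise ValueError("reference dose must be present in the table")
    frames = []
    for dose, df in sorted(metrics_by_dose.items()):
        sub = df[["id", "auc24"]].copy()
        sub.insert(0, "dose_mg", dose)
        sub["dnauc"] = reference * sub["auc24"] / dose
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    summary = (
        long.groupby("dose_mg")["dnauc"].quantile([0.05, 0.5, 0.95]).unstack()
    )
    return long, summary
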