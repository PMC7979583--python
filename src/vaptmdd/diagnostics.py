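"""Model-evaluation utilities: inhibition transform, VPC, effect curve.

The visual predictive check (VPC) re-simulates the original dataset design
``n_rep`` times with fresh random effects and residual noise and compares
the observed 5th/50th/95th percentiles with the distribution of the same
percentiles across replicates, per scheduled time and stratum.

The concentration-effect curve maps the assay-visible total ASP8232 plasma
concentration to the predicted VAP-1 inhibition: for a total central drug
concentration the quasi-equilibrium free-target fraction sets the free
soluble VAP-1, the power model sets activity, and inhibition is expressed
against the drug-free baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .binding import free_fraction
from .cohort import sample_etas
from .covariates import apply_covariates
from .estimation import _build_groups, _predict_group
from .parameters import ModelParameters, OmegaSigma, Subject
from .units import ng_per_mL_to_nM

__all__ = [
    "inhibition_percent",
    "vpc",
    "VPCBands",
    "concentration_effect_curve",
    "ConcentrationEffectResult",
]


def inhibition_percent(baseline_activity, activity):
    """Percent inhibition relative to a (pre-dose median) baseline.

    ``100 * (baseline - activity) / baseline``; negative values are allowed
    (measurement error can push observed activity above baseline).
    """
    baseline = np.asarray(baseline_activity, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline activity must be strictly positive")
    return 100.0 * (baseline - np.asarray(activity, dtype=float)) / baseline


@dataclass
class VPCBands:
    """Percentile bands per (stratum, observation type, scheduled time).

    ``table`` columns: stratum, type, time, n_obs, obs_p5/p50/p95, and for
    each simulated percentile its median and 90% interval across replicates
    (sim_p50_med, sim_p50_lo, sim_p50_hi, ...).  Values are on the natural
    (exponentiated) scale.
    """

    table: pd.DataFrame
    n_rep: int


def vpc(
    dataset: pd.DataFrame,
    theta: ModelParameters,
    omega_sigma: OmegaSigma,
    n_rep: int = 100,
    seed=None,
    strata_cols=("PHASE",),
) -> VPCBands:
    """Visual-predictive-check bands from replicate simulations.

    Re-simulates every subject's design with fresh etas (full omega block)
    and residual noise, then summarizes observed and simulated 5th/50th/
    95th percentiles per observation type, stratum and scheduled time.
    Strata/time cells with fewer than 2 observations are omitted with a
    warning.
    """
    rng = np.random.default_rng(seed)
    groups = _build_groups(dataset)
    # Stratum label per subject from the dataset columns.
    first = dataset.groupby("ID").first()
    strat_of = {
        sid: "/".join(str(first.loc[sid][c]) for c in strata_cols) if strata_cols else "all"
        for sid in first.index
    }

    obs_rows = []
    sim_rows = []
    for g in groups:
        n = len(g.subjects)
        all_etas = sample_etas(omega_sigma.omega, n * n_rep, rng)
        for rep in range(n_rep):
            etas = all_etas[rep * n : (rep + 1) * n]
            preds = _predict_group(g, theta, etas)
            for i, sd in enumerate(g.subjects):
                phase2 = sd.subject.study_phase == "phase2"
                sig = np.sqrt(
                    [omega_sigma.sigma2_for(t, phase2) for t in sd.obs_types]
                )
                dv_sim = preds[i] + rng.normal(0.0, 1.0, size=len(sig)) * sig
                for t, typ, v in zip(sd.obs_times, sd.obs_types, dv_sim):
                    sim_rows.append((strat_of[sd.subject.id], typ, t, rep, np.exp(v)))
        for sd in g.subjects:
            for t, typ, v in zip(sd.obs_times, sd.obs_types, sd.dv):
                obs_rows.append((strat_of[sd.subject.id], typ, t, np.exp(v)))

    obs = pd.DataFrame(obs_rows, columns=["stratum", "type", "time", "value"])
    sim = pd.DataFrame(sim_rows, columns=["stratum", "type", "time", "rep", "value"])

    records = []
    for (stratum, typ, time), o in obs.groupby(["stratum", "type", "time"]):
        if len(o) < 2:
            warnings.warn(
                f"VPC stratum {stratum!r} type {typ!r} t={time}: "
                f"fewer than 2 observations; percentiles omitted",
                UserWarning,
            )
            continue
        s = sim[(sim["stratum"] == stratum) & (sim["type"] == typ) & (sim["time"] == time)]
        per_rep = s.groupby("rep")["value"].quantile([0.05, 0.5, 0.95]).unstack()
        rec = {
            "stratum": stratum,
            "type": typ,
            "time": time,
            "n_obs": len(o),
            "obs_p5": o["value"].quantile(0.05),
            "obs_p50": o["value"].quantile(0.5),
            "obs_p95": o["value"].quantile(0.95),
        }
        for q, name in ((0.05, "p5"), (0.5, "p50"), (0.95, "p95")):
            col = per_rep[q]
            rec[f"sim_{name}_med"] = col.median()
            rec[f"sim_{name}_lo"] = col.quantile(0.05)
            rec[f"sim_{name}_hi"] = col.quantile(0.95)
        records.append(rec)
    cols = ["stratum", "type", "time", "n_obs", "obs_p5", "obs_p50", "obs_p95"] + [
        f"sim_{n}_{s}" for n in ("p5", "p50", "p95") for s in ("med", "lo", "hi")
    ]
    table = pd.DataFrame(records, columns=cols)
    table = table.sort_values(["stratum", "type", "time"]).reset_index(drop=True)
    return VPCBands(table=table, n_rep=n_rep)


@dataclass
class ConcentrationEffectResult:
    """Predicted concentration-inhibition relationship."""

    conc_ng_ml: np.ndarray
    inhibition_pct: np.ndarray
    ic50_ng_ml: float  # measured total concentration at 50% inhibition


def _measured_from_total(c_tot_nM: float, tvap1: float, svap1: float, kd: float) -> float:
    phi = free_fraction(c_tot_nM, tvap1, kd)
    return phi * c_tot_nM + (1.0 - phi) * c_tot_nM * (svap1 / tvap1)


def _inhibition_at_total(c_tot_nM, tvap1, svap1, pow_, kd):
    phi_t = free_fraction(tvap1, c_tot_nM, kd)
    return 100.0 * (1.0 - phi_t**pow_)


def concentration_effect_curve(
    theta: ModelParameters,
    conc_grid_ng_ml,
    sex: str = "male",
) -> ConcentrationEffectResult:
    """Predicted inhibition versus measured total plasma concentration.

    The grid is in assay (ng/mL) units of the total plasma concentration
    (free drug plus soluble-target-bound complex); each point is inverted
    to the underlying total central concentration before evaluating the
    free-target fraction.  The activity slope SL cancels out of the
    inhibition ratio, leaving the relationship governed by KD, the target
    pools and POW.
    """
    ip = apply_covariates(theta, Subject(sex=sex, egfr=theta.egfr_ref_f1))
    tv, sv, kd, pw = ip.tVAP1c, ip.sVAP1c, ip.KD, ip.POW
    grid = np.asarray(conc_grid_ng_ml, dtype=float)
    if np.any(grid < 0):
        raise ValueError("concentration grid must be non-negative")

    def total_from_measured(meas_ng_ml: float) -> float:
        if meas_ng_ml <= 0:
            return 0.0
        m = ng_per_mL_to_nM(meas_ng_ml)
        hi = m + tv + kd + 1.0
        return optimize.brentq(
            lambda c: _measured_from_total(c, tv, sv, kd) - m, 0.0, hi, xtol=1e-12
        )

    inh = np.array(
        [_inhibition_at_total(total_from_measured(g), tv, sv, pw, kd) for g in grid]
    )

    def inh_of_meas(meas):
        return _inhibition_at_total(total_from_measured(meas), tv, sv, pw, kd)

    ic50 = optimize.brentq(lambda m: inh_of_meas(m) - 50.0, 1e-6, 1e4, xtol=1e-10)
    return ConcentrationEffectResult(grid, inh, float(ic50))
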