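"""Simulation layer: linear-limit oracles, metrics, population runs."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from vaptmdd import (
    Subject,
    apply_covariates,
    average_inhibition_24h,
    build_regimen,
    daily_regimen,
    dose_normalized_auc,
    mg_to_nmol,
    secondary_params,
    simulate_population,
    simulate_profile,
    steady_state_grid,
)
from vaptmdd.model import ode_rhs, pack_individual
from vaptmdd.parameters import IndividualParameters
from vaptmdd.simulate import ProfileResult, simulate_states


def _linear_params(**kw):
    # Target pools at zero: the TMDD system collapses to a linear
    # three-compartment model with transit absorption.
    base = dict(
        ka=3.12, LAG=0.31, CL=17.6, V2=210.0, V3=210.0, V4=26.7,
        Q=37.6, Q2=80.5, KD=0.929, sVAP1c=5.52, tVAP1c=0.0,
        mVAP1p1=0.0, mVAP1p2=0.0, SL=851.0, POW=0.851, f1_rel=1.0,
    )
    base.update(kw)
    return IndividualParameters(**base)


def _linear_matrix(p):
    ka, k20, k23, k32, k24, k42 = p.ka, p.k20, p.k23, p.k32, p.k24, p.k42
    return np.array(
        [
            [-ka, 0, 0, 0, 0],
            [ka, -ka, 0, 0, 0],
            [0, ka, -(k20 + k23 + k24), k32, k42],
            [0, 0, k23, -k32, 0],
            [0, 0, k24, 0, -k42],
        ]
    )


def test_linear_limit_matches_matrix_exponential(typical_subject):
    p = _linear_params()
    reg = build_regimen([(0.0, 40.0)])
    grid = np.array([1.0, 2.0, 6.0, 12.0, 24.0, 48.0, 96.0])
    states = simulate_states([p], reg, grid)
    A = _linear_matrix(p)
    y0 = np.array([mg_to_nmol(40.0), 0, 0, 0, 0])
    for g, s in zip(grid, states[:, 0, :]):
        exact = expm(A * (g - p.LAG)) @ y0
        np.testing.assert_allclose(s, np.maximum(exact, 0), rtol=1e-3, atol=1e-6)
        # headline check at the spec'd 0.1% on the central amount
        assert s[2] == pytest.approx(exact[2], rel=1e-3)


def test_linear_limit_superposition():
    p = _linear_params()
    grid = np.arange(0.0, 7 * 24.0, 2.0)
    reg1 = daily_regimen(10.0, 7)
    reg2 = daily_regimen(20.0, 7)
    s1 = simulate_states([p], reg1, grid)
    s2 = simulate_states([p], reg2, grid)
    np.testing.assert_allclose(2 * s1, s2, rtol=1e-3, atol=1e-8)


def test_kernel_matches_scipy_on_nonlinear_regimen(typical_ip):
    # Independent route: piecewise LSODA on the reference RHS.
    reg = build_regimen("0002-part2")
    grid = np.array([2.0, 12.0, 24.0, 25.0, 100.0, 27 * 24.0, 28 * 24.0])
    states = simulate_states([typical_ip], reg, grid)
    events = [(t + typical_ip.LAG, mg_to_nmol(a) * typical_ip.f1_rel) for t, a in reg.events]
    bps = sorted(set(e[0] for e in events) | set(grid))
    y, t = np.zeros(5), 0.0
    oracle = {}
    for tb in bps:
        if tb > t:
            sol = solve_ivp(
                ode_rhs, (t, tb), y, args=(typical_ip,), method="LSODA",
                rtol=1e-10, atol=1e-12,
            )
            y, t = sol.y[:, -1], tb
        if tb in grid:
            oracle[tb] = y.copy()
        for te, amt in events:
            if te == tb:
                y[0] += amt
    for i, g in enumerate(grid):
        np.testing.assert_allclose(states[i, 0], oracle[g], rtol=1e-5, atol=1e-6)


def test_zero_dose_profile_is_flat_baseline(typical_ip):
    prof = simulate_profile(typical_ip, [], 48.0)
    assert np.all(prof.conc_drug_total == 0.0)
    np.testing.assert_allclose(prof.activity, typical_ip.baseline_activity, rtol=1e-12)
    np.testing.assert_allclose(prof.inhibition, 0.0, atol=1e-9)


def test_steady_state_auc_matches_closed_form_in_linear_limit():
    # With no target, AUC over the final daily interval at steady state is
    # f1 * Dose / CL exactly (clearance acts on the full concentration).
    p = _linear_params(f1_rel=1.1)
    weeks = 8
    reg = daily_regimen(40.0, weeks * 7)
    prof = simulate_profile(p, reg, weeks * 168.0, steady_state_grid(weeks))
    sp = secondary_params(prof, reg)
    analytic = 1.1 * mg_to_nmol(40.0) / p.CL * 0.444  # nM*h -> ng*h/mL
    assert sp.auc24_52w == pytest.approx(analytic, rel=1e-3)


def test_trapezoid_auc_against_quadrature_oracle(typical_ip):
    # One-off check of the 0.1 h trapezoid against an integrator that
    # carries the measured concentration as an extra quadrature state.
    from vaptmdd.model import predict_observations

    reg = daily_regimen(10.0, 3)
    grid = np.arange(48.0, 72.0 + 1e-9, 0.1)
    prof = simulate_profile(typical_ip, reg, 72.0, grid)
    auc_trap = np.trapezoid(prof.conc_drug_total, prof.times)

    def rhs_aug(t, y):
        dy = np.zeros(6)
        dy[:5] = ode_rhs(t, y[:5], typical_ip)
        log_drug, _, _ = predict_observations(np.maximum(y[:5], 0.0), typical_ip)
        dy[5] = np.exp(log_drug) * 0.444 if np.isfinite(log_drug) else 0.0
        return dy

    y, t = np.zeros(6), 0.0
    events = [(tt + typical_ip.LAG, mg_to_nmol(a) * typical_ip.f1_rel) for tt, a in reg.events]
    for tb in sorted(set(e[0] for e in events) | {48.0, 72.0}):
        sol = solve_ivp(rhs_aug, (t, tb), y, method="LSODA", rtol=1e-10, atol=1e-12)
        y, t = sol.y[:, -1], tb
        if tb == 48.0:
            auc_start = y[5]
        for te, amt in events:
            if te == tb:
                y[0] += amt
    auc_exact = y[5] - auc_start
    assert auc_trap == pytest.approx(auc_exact, rel=5e-4)


def test_secondary_params_definitions(typical_ip):
    reg = daily_regimen(10.0, 14)
    prof = simulate_profile(typical_ip, reg, 14 * 24.0, steady_state_grid(2))
    sp = secondary_params(prof, reg)
    assert sp.t_half_apparent == sp.tss / 5.0
    assert 0.0 <= sp.tmax_52w <= 24.0


def test_constant_profile_reaches_steady_state_immediately():
    reg = daily_regimen(1.0, 14)
    grid = steady_state_grid(2)
    const = ProfileResult(
        times=grid,
        conc_drug_total=np.full(grid.size, 5.0),
        conc_svap1=np.full(grid.size, 5.52),
        activity=np.full(grid.size, 100.0),
        inhibition=np.zeros(grid.size),
        baseline_activity=100.0,
    )
    sp = secondary_params(const, reg)
    assert sp.tss == pytest.approx(24.0 / 168.0)  # first examined trough


def test_secondary_params_requires_full_final_interval(typical_ip):
    reg = daily_regimen(10.0, 14)
    short = simulate_profile(typical_ip, reg, 14 * 24.0, np.arange(0.0, 300.0, 0.1))
    with pytest.raises(ValueError):
        secondary_params(short, reg)


def test_average_inhibition_edge_cases():
    t = np.arange(0.0, 25.0, 0.5)
    zero = ProfileResult(t, np.zeros(t.size), np.zeros(t.size),
                         np.full(t.size, 100.0), np.zeros(t.size), 100.0)
    assert average_inhibition_24h(zero, (0.0, 24.0)) == 0.0
    pinned = ProfileResult(t, np.zeros(t.size), np.zeros(t.size),
                           np.full(t.size, 10.0), np.full(t.size, 90.0), 100.0)
    assert average_inhibition_24h(pinned, (0.0, 24.0)) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        average_inhibition_24h(zero, (10.0, 10.0))
    with pytest.raises(ValueError):
        average_inhibition_24h(zero, (0.0, 99.0))


def test_population_zero_omega_identical_subjects(theta):
    cohort = [Subject(id=i, sex="male", egfr=44.0) for i in range(4)]
    m = simulate_population(theta, np.zeros((3, 3)), cohort, 10.0, weeks=2, seed=1)
    assert m["auc24"].nunique() == 1
    assert m["avg_inhibition_24h"].nunique() == 1


def test_dose_normalized_auc_table(theta, typical_subject):
    import pandas as pd

    mk = lambda auc: pd.DataFrame({"id": [1], "auc24": [auc]})
    long, summary = dose_normalized_auc({40.0: mk(2320.0), 10.0: mk(620.0)}, 40.0)
    ref_row = long[long.dose_mg == 40.0].iloc[0]
    assert ref_row["dnauc"] == ref_row["auc24"]  # reference dose: AUC itself
    assert long[long.dose_mg == 10.0]["dnauc"].iloc[0] == pytest.approx(4 * 620.0)
    with pytest.raises(ValueError):
        dose_normalized_auc({10.0: mk(1.0)}, 40.0)
    with pytest.raises(ValueError):
        dose_normalized_auc({0.0: mk(1.0), 40.0: mk(1.0)}, 40.0)


def test_linear_limit_dose_normalized_ratio_is_one():
    p = _linear_params()
    aucs = {}
    for d in (1.0, 40.0):
        reg = daily_regimen(d, 14)
        prof = simulate_profile(p, reg, 14 * 24.0, steady_state_grid(2))
        aucs[d] = secondary_params(prof, reg).auc24_52w
    assert 40.0 * aucs[1.0] / 1.0 == pytest.approx(aucs[40.0], rel=1e-3)


def test_steady_state_time_shortens_with_dose(typical_ip):
    # Target-mediated clearance saturates with dose, so accumulation is
    # slower (longer Tss) at low doses.
    tss = []
    for d in (0.1, 1.0, 10.0, 40.0):
        reg = daily_regimen(d, 364)
        prof = simulate_profile(typical_ip, reg, 364 * 24.0, steady_state_grid(52))
        tss.append(secondary_params(prof, reg).tss)
    assert all(a >= b for a, b in zip(tss, tss[1:]))
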