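"""Structural model: ODE right-hand side and observation equations.

State vector (amounts in nmol): A1 depot, At transit, A2 central (total
drug, free + target-bound), A3 first peripheral, A4 second peripheral.
Absorption runs depot -> transit -> central, both steps at rate ka, with
each dose's administration time shifted by LAG.  Distribution and
elimination act on the *free* drug only: every linear rate constant is
multiplied by the quasi-equilibrium free fraction in its source
compartment, evaluated against that compartment's target pool.

This module is the plain-Python reference implementation; the production
integrator (:mod:`vaptmdd._kernel`) evaluates the same equations under
numba and is cross-checked against this path in the test suite.
"""

from __future__ import annotations

import numpy as np

from .binding import free_fraction
from .parameters import IndividualParameters

__all__ = ["ode_rhs", "predict_observations", "pack_individual"]


def ode_rhs(t: float, state, params: IndividualParameters) -> np.ndarray:
    """d(state)/dt at time ``t`` (autonomous; ``t`` kept for solver APIs)."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    a1, at, a2, a3, a4 = state
    p = params
    phi_c = free_fraction(max(a2, 0.0) / p.V2, p.tVAP1c, p.KD)
    phi_p1 = free_fraction(max(a3, 0.0) / p.V3, p.mVAP1p1, p.KD)
    phi_p2 = free_fraction(max(a4, 0.0) / p.V4, p.mVAP1p2, p.KD)
    out_c = phi_c * (p.k20 + p.k23 + p.k24) * a2
    return np.array(
        [
            -p.ka * a1,
            p.ka * a1 - p.ka * at,
            p.ka * at - out_c + phi_p1 * p.k32 * a3 + phi_p2 * p.k42 * a4,
            phi_c * p.k23 * a2 - phi_p1 * p.k32 * a3,
            phi_c * p.k24 * a2 - phi_p2 * p.k42 * a4,
        ]
    )


def predict_observations(state, params: IndividualParameters):
    """Log-scale predictions (drug, sVAP-1, activity) from one state.

    * drug: log of the assay-visible total plasma concentration (nM) —
      free drug plus the sVAP-1-bound share of the complex, the latter
      weighted by sVAP1c / tVAP1c since soluble and membrane-bound target
      share one KD.  Undefined (-inf) at A2 = 0.
    * sVAP-1: log of the total soluble target concentration, constant under
      the no-turnover assumption.
    * activity: log of SL * (free sVAP-1)^POW with free sVAP-1 =
      phi_tVAP1 * sVAP1c.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("amounts must be non-negative")
    a2 = state[2]
    p = params
    c2 = a2 / p.V2
    phi_c = free_fraction(c2, p.tVAP1c, p.KD)
    w = p.sVAP1c / p.tVAP1c
    meas = phi_c * c2 + (1.0 - phi_c) * c2 * w
    log_drug = np.log(meas) if meas > 0 else -np.inf
    phi_t = free_fraction(p.tVAP1c, c2, p.KD)
    log_act = np.log(p.SL * (phi_t * p.sVAP1c) ** p.POW)
    return log_drug, np.log(p.sVAP1c), log_act


def pack_individual(p: IndividualParameters) -> np.ndarray:
    """Flatten an individual's parameters for the numba kernel.

    Layout: [ka, k20, k23, k32, k24, k42, V2, V3, V4,
             tVAP1c, mVAP1p1, mVAP1p2, KD, sVAP1c, SL, POW, f1_rel]
    """
    return np.array(
        [
            p.ka,
            p.k20,
            p.k23,
            p.k32,
            p.k24,
            p.k42,
            p.V2,
            p.V3,
            p.V4,
            p.tVAP1c,
            p.mVAP1p1,
            p.mVAP1p2,
            p.KD,
            p.sVAP1c,
            p.SL,
            p.POW,
            p.f1_rel,
        ]
    )
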