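"""Quasi-equilibrium binding algebra.

With binding at equilibrium, the free fraction of a species in the presence
of a binding partner follows from the mass-balance quadratic

    C_free * (1 + T_total / (KD + C_free_partner)) = C_total,

whose physical root has the closed form

    phi = (C - T - KD + sqrt((C - T - KD)^2 + 4*KD*C)) / (2*C),

where C is the total concentration of the species of interest and T the
total concentration of its partner.  The expression is symmetric in form
between drug and target.  At C -> 0 the closed form is 0/0; the analytic
limit is KD / (KD + T).
"""

from __future__ import annotations

import numpy as np

__all__ = ["free_fraction", "free_fraction_drug", "free_fraction_target"]

# Below this total concentration (nM) the analytic zero-limit is used; the
# closed form loses all precision near 0/0 while the limit is exact to
# O(C/KD).
_ZERO_LIMIT = 1e-12


def free_fraction(c_total: float, partner_total: float, kd: float) -> float:
    """Free fraction of a species bound by ``partner_total`` at ``kd``.

    Scalar, branch-stable evaluation: when the linear coefficient of the
    quadratic is negative the conjugate form ``2*KD / (sqrt(b^2+4*KD*C)-b)``
    avoids catastrophic cancellation.
    """
    if kd <= 0:
        raise ValueError("kd must be strictly positive")
    if c_total < 0 or partner_total < 0:
        raise ValueError("concentrations must be non-negative")
    if c_total < _ZERO_LIMIT:
        return kd / (kd + partner_total)
    b = c_total - partner_total - kd
    s = np.sqrt(b * b + 4.0 * kd * c_total)
    if b >= 0.0:
        return min((b + s) / (2.0 * c_total), 1.0)
    return min(2.0 * kd / (s - b), 1.0)


def free_fraction_drug(c_total_drug, c_total_target, kd):
    """Fraction of total drug that is unbound (phi_drug)."""
    return free_fraction(c_total_drug, c_total_target, kd)


def free_fraction_target(c_total_target, c_total_drug, kd):
    """Fraction of total target that is unbound (phi_tVAP1)."""
    return free_fraction(c_total_target, c_total_drug, kd)
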