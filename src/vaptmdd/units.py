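"""Molar-unit conversions for ASP8232.

All internal model quantities are molar: drug amounts in nmol, drug and
target concentrations in nM.  Doses are entered in mg and assay-scale drug
concentrations are reported in ng/mL, using the free-base molecular weight
of 444 g/mol (so 1 nM = 0.444 ng/mL).
"""

from __future__ import annotations

import numpy as np

#: Molecular weight of the ASP8232 free base (g/mol).
MW_ASP8232 = 444.0


def _check_nonneg(x, name: str):
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be non-negative")


def mg_to_nmol(dose_mg):
    """Convert an ASP8232 dose in mg to nmol (MW 444 g/mol)."""
    _check_nonneg(dose_mg, "dose_mg")
    return np.multiply(dose_mg, 1e6 / MW_ASP8232)


def nM_to_ng_per_mL(conc_nM):
    """Convert an ASP8232 concentration from nM to ng/mL."""
    _check_nonneg(conc_nM, "concentration")
    return np.multiply(conc_nM, MW_ASP8232 / 1000.0)


def ng_per_mL_to_nM(conc_ng_mL):
    """Convert an ASP8232 concentration from ng/mL to nM."""
    _check_nonneg(conc_ng_mL, "concentration")
    return np.multiply(conc_ng_mL, 1000.0 / MW_ASP8232)
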