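"""Concentration-effect relationship and the half-inhibition concentration.

Maps total ASP8232 plasma concentration (the assay-visible free drug plus
soluble-target-bound complex) to predicted VAP-1 inhibition through the
quasi-equilibrium free-target fraction and the activity power model.  The
curve is steepest around 1-5 ng/mL: half-inhibition near 2 ng/mL and
near-complete inhibition above 50 ng/mL.
"""

import numpy as np

from vaptmdd import concentration_effect_curve, default_parameters

theta = default_parameters()
grid = np.array([0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0])
res = concentration_effect_curve(theta, grid)

for c, i in zip(res.conc_ng_ml, res.inhibition_pct):
    print(f"{c:>6.1f} ng/mL -> {i:5.1f} % inhibition")
print(f"\n50% inhibition at {res.ic50_ng_ml:.2f} ng/mL total plasma concentration")
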