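"""Population dose-response of VAP-1 inhibition in virtual DKD patients.

Draws a virtual cohort matching the phase-2 DKD study population (77.5%
male, eGFR ~ truncated normal around 44), samples random effects from the
full omega block, and simulates 52 weeks of daily dosing per dose level.
The printed median and 5th/95th percentiles of the average 24-h inhibition
show >90% inhibition for doses of 3 mg and above, dropping below 50% near
0.2-0.3 mg.
"""

from dataclasses import replace

from vaptmdd import (
    ALBUM_POPULATION,
    default_omega_sigma,
    default_parameters,
    sample_covariates,
    simulate_population,
)

theta = default_parameters()
osig = default_omega_sigma()
cohort = sample_covariates(replace(ALBUM_POPULATION, n=300), seed=17)

print(f"{'dose (mg)':>10} {'p5':>7} {'median':>7} {'p95':>7}   average 24-h inhibition (%)")
for dose in (0.1, 0.3, 1.0, 3.0, 10.0, 40.0):
    metrics = simulate_population(theta, osig.omega, cohort, dose, weeks=52, seed=18)
    q = metrics["avg_inhibition_24h"].quantile([0.05, 0.5, 0.95])
    print(f"{dose:>10g} {q[0.05]:>7.1f} {q[0.5]:>7.1f} {q[0.95]:>7.1f}")
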