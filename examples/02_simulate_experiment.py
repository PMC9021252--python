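"""Synthetic mother-machine experiment with known ground truth.

Draws 40 cells from the default two-component (ln u, ln d) population,
simulates noisy fluorescence traces on the standard acquisition grid, and
summarizes the population the way a condition table would."""

import numpy as np

from nbdgkin import (
    ExperimentDesign,
    NoiseSpec,
    coefficient_of_variation,
    default_population,
    pearson_r,
    simulate_experiment,
    steady_state_mean,
)

traces, profile, params = simulate_experiment(
    default_population(), ExperimentDesign(), NoiseSpec(), n_cells=40, seed=7
)

mean, sem, n = steady_state_mean(traces, t_query=900.0)
vals_900 = [tr.values[np.argmin(np.abs(tr.times - 900.0))] for tr in traces]
logs = np.array([p.log for p in params])
r, p = pearson_r(logs[:, 0], logs[:, 1])

print(f"simulated {n} cells, {len(traces[0])} frames each (every 20 s to 2100 s)")
print(f"steady-state fluorescence at t=900 s: {mean:.0f} ± {sem:.0f} a.u. (mean ± SEM)")
print(f"population CV at t=900 s:             {coefficient_of_variation(vals_900):.0f}%")
print(f"true ln u vs ln d Pearson r:          {r:.2f} (p = {p:.1e})")

# The CV of tens of percent reflects the mixture population: a slower
# majority component and a faster-metabolizing subset, which also induces
# the positive uptake-degradation correlation across the whole population.
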