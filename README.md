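# nbdgkin

Single-cell glucose-analogue (2-NBDG) uptake/degradation kinetics: an exact
forward model, a synthetic mother-machine experiment generator, per-cell
maximum-likelihood fits, and a hierarchical Bayesian sampler whose population
prior is an infinite Gaussian mixture — plus the bulk-assay computations
(one-phase decay time constants, colorimetric glucose concentrations) and the
population summary statistics that go with them.

## Who this is for

Groups measuring time-lapse fluorescence of individual bacteria in
mother-machine microfluidics while a fluorescent glucose analogue is added
(here: 30 µM 2-NBDG at t = 0) and later washed out (t = 1200 s). Each cell's
trace rises to a steady state set by the balance of uptake and intracellular
degradation, then decays after washout. The package turns those traces into
per-cell rate constants with calibrated uncertainty, and quantifies
population structure (subpopulations, heterogeneity, rate correlations)
without committing to a parametric population shape.

## Model

Per cell `i`, intracellular concentration follows

    d[gluc]_in/dt = − d_gluc,i [gluc]_in + (u_gluc,i / V_c,i) [gluc]_ex(t)

with uptake rate `u_gluc` (µm³/s), degradation rate `d_gluc` (1/s), and
spherocylinder volume `V_c` from the cell's width and length. `[gluc]_ex(t)`
is piecewise linear, so the ODE is solved exactly segment by segment.
Observations are Gaussian with SD proportional to the signal
(`σ = max(CV_error·[gluc], floor)`). Per-cell `(ln u, ln d)` receive a
Dirichlet-process Gaussian-mixture prior whose hyperparameters
(α, λ, r, β, w) are sampled along with everything else in a
Metropolis-within-Gibbs scheme initialized at per-cell Levenberg–Marquardt
estimates. See `docs/methods.md` for the full model, priors, conventions and
limitations.

## Worked example

```python
import numpy as np
from nbdgkin import (ExperimentDesign, InferenceConfig, NoiseSpec,
                     default_population, run_inference, simulate_experiment)

traces, profile, params = simulate_experiment(
    default_population(), ExperimentDesign(), NoiseSpec(), n_cells=20, seed=11)
truth = np.array([p.log for p in params])

draws = run_inference(traces, profile,
                      InferenceConfig(n_iterations=1500, n_burnin=600, seed=11))
rmse = np.sqrt(np.mean((draws.medians() - truth) ** 2))
print(f"posterior-median RMSE vs truth: {rmse:.3f} log-units")
print(f"mean MH acceptance rate: {draws.accept_rate.mean():.2f}")
```

prints

```
posterior-median RMSE vs truth: 0.007 log-units
mean MH acceptance rate: 0.31
```

i.e. per-cell log-rates are recovered to better than 1% at the default 5%
measurement noise, with the random-walk proposal adapted into its healthy
acceptance band. The scripts in `examples/` walk through each capability —
forward model, synthetic experiments, MLE, hierarchical inference, bulk
assays — and print a line or two explaining every number they compute.

A thin CLI mirrors the pipeline for shell use:

```bash
nbdgkin simulate --config config.yaml --out sim/
nbdgkin infer --traces sim/traces.csv --profile sim/profile.csv --out posterior.json
nbdgkin summarize --traces sim/traces.csv --posterior posterior.json --out summary.csv
nbdgkin decay-fit --data decay.csv --out tau.json
nbdgkin assay --standards std.csv --samples smp.csv --out conc.csv
```

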