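# Methods

## Kinetic model

Intracellular concentration of the fluorescent glucose analogue 2-NBDG in a
single rod-shaped bacterium is modelled by first-order uptake and
degradation:

    d[gluc]_in/dt = -d_gluc [gluc]_in + (u_gluc / V_c) [gluc]_ex(t)

- `u_gluc` (µm³ s⁻¹): uptake rate constant, first order in the extracellular
  concentration. Only the ratio `u_gluc / V_c` enters the dynamics, so the
  uptake rate is identified jointly with the cell volume.
- `d_gluc` (s⁻¹): degradation rate constant (phosphorylation and downstream
  glycolytic processing of the analogue).
- `V_c` (µm³): cell volume from the measured width `w` (diameter) and
  pole-to-pole length `l`, treated as a spherocylinder,
  `V = π(w/2)²(l−w) + (4/3)π(w/2)³`. A plain-cylinder option exists for
  sensitivity checks. Widths near 1 µm follow from confinement in the
  1-µm hosting channels.
- `[gluc]_ex(t)`: extracellular concentration, a piecewise-linear function
  of time shared by all cells in an experiment. Knot times may repeat to
  encode instantaneous steps (evaluated right-continuously); outside the
  knot range the profile clamps to its boundary values.

Fluorescence (a.u.) is taken proportional to concentration with
proportionality 1, so `u_gluc` carries a.u.-consistent units; the initial
condition is `[gluc]_in(0) = 0` (cells are analogue-naive at addition).

Because the forcing is piecewise linear, the ODE is solved *exactly*: the
output grid is merged with the profile knots, and on each segment with
forcing `g(τ) = a + bτ` the closed form

    y(h) = y0 e^{-dh} + (u/V)[a(1-e^{-dh})/d + b(h/d - (1-e^{-dh})/d²)]

is applied (expm1-based, so small `d·h` is accurate). This is unconditionally
stable and ~20 µs per trace, which makes the Monte Carlo affordable. The
idealized two-branch step solution (instant addition at t=0, instant washout
at t=t₁) is also provided; with zero ramp times the segment solver reproduces
it to machine precision.

## Measurement model

An observation `y_t` is Normal with mean `[gluc]_t` and standard deviation
`σ_t = max(cv_error · [gluc]_t, sigma_floor)`. Defaults: `cv_error = 0.05`
(a value of this order is typical for background-subtracted single-cell
fluorescence; the source protocol does not fix one) and
`sigma_floor = 0.3 a.u.` (1% of the 30-µM plateau in signal units). The floor
exists because purely multiplicative noise is degenerate at zero signal —
without it the likelihood assigns infinite density at t = 0.

## Synthetic experiments

The generator reproduces the acquisition protocol of the microfluidics
assay: frames every 20 s from analogue addition at t = 0 to t = 2100 s,
30 µM plateau, washout beginning at t = 1200 s. Media exchange is not
instantaneous (flow ramps over minutes), so the default profile rises and
falls linearly over 120 s; zero ramps give the ideal step.

Per-cell `(ln u, ln d)` come from a two-component Gaussian mixture:
means (−1.35, −5.30) and (−0.35, −4.30), weights 0.6/0.4, within-component
SD 0.25 log-units, within-component correlation 0. The slower component
yields steady-state fluorescence of a few hundred a.u. with accumulation
time constant `1/d ≈ 200 s` (saturating by ~900 s); the second sits one
log-unit higher in both rates — a faster-metabolizing subpopulation. Two
consequences are intentional: population CVs land in the tens of percent,
and a positive population-level correlation between ln u and ln d *emerges*
from the mixture rather than being imposed within components. Imposing it
within components would also tilt each cluster along the inter-component
axis and erode the effective (Mahalanobis) separation that makes
subpopulation recovery a well-posed test. Geometries are truncated normals
(width 1.0 ± 0.05 µm on [0.8, 1.2]; length 2.5 ± 0.5 µm on [1.4, 5.0],
floored at the width).

What the generator does **not** emulate: photobleaching, cell growth and
division (dilution), lineage correlations, segmentation errors, spatial
concentration gradients in the channels, or non-Gaussian outliers. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated model, not robustness to those real-data
effects.

## Per-cell point estimates

`mle_fit` minimizes squared residuals of the forward model against one
trace, parameterized in `(ln u, ln d)` so positivity is automatic, using
Levenberg–Marquardt with an iteration cap of 15 (configurable). The start
point is heuristic: the plateau level fixes `u/(dV_c)`; the post-washout
log-linear decay slope (or, failing that, the accumulation half-time) fixes
`d`. Traces with no signal raise a non-identifiability error rather than
returning a junk fit. On noiseless synthetic traces the round-trip error is
at floating-point level; at 5% multiplicative noise the median relative
error over 40 cells is ~1%.

## Hierarchical model and sampler

Per-cell log-parameters `x_i = (ln u_i, ln d_i)` receive an infinite
Gaussian mixture (Dirichlet-process) population prior:

    x_i | c_i=j ~ N(μ_j, S_j⁻¹)        μ_j ~ N(λ, r⁻¹)
    S_j ~ Wishart(df=β, scale=(βw)⁻¹)   c ~ CRP(α)

with hyperpriors λ ~ N(μ₀, Σ₀), r ~ Wishart(Σ₀⁻¹/2, 2),
w ~ Wishart(Σ₀/2, 2), (β−1) ~ Gamma(1,1), α ~ Gamma(1,1). Conventions:
Wishart(scale, df) with mean df·scale — stated explicitly because the
hyperprior table this follows does not fix one. (μ₀, Σ₀) are the sample mean
and ridge-regularized covariance (ridge 1e-6) of the per-cell MLEs. The
log-space placement of the mixture guarantees positive rates and matches how
the rates are summarized (natural logs). An alternative reading of the β
hyperprior — Gamma(1,1) on 1/β restricted to β>1 — is available as
`beta_prior="inverse_gamma"`; the package does not guess which was meant and
defaults to the shifted-Gamma reading.

Sampling alternates:

- **(a) per-cell Metropolis–Hastings.** One Gaussian random-walk step on
  `x_i` against likelihood × conditional mixture prior (occupied components
  weighted by membership counts excluding cell i, concentration mass α
  spread over `n_aux = 3` auxiliary prior draws), followed by a Gibbs
  refresh of the cell's component assignment — the auxiliary-component
  (algorithm-8) treatment of unrepresented clusters. The proposal is a
  per-cell diagonal step adapted toward 30% acceptance during burn-in
  (Robbins–Monro on the log step) and frozen afterwards, so retained draws
  satisfy detailed balance.
- **(b) population sweep.** Assignments (algorithm 8), then conjugate draws
  for each occupied component's mean and precision, then λ, r, w from their
  conjugate conditionals; β and α by Metropolis steps on log(β−1) and log α
  against their exact conditionals (simpler than adaptive rejection
  sampling, same stationary distribution).

Defaults: 5000 sweeps, 2000 burn-in, no thinning. Chains start at the MLEs
with one mixture component **per cell**: merging redundant components is an
easy move for incremental Gibbs, whereas splitting an under-fitted component
is a rare-event sequence, so the fully-split start makes burn-in reliable.

Numerical notes. All 2×2 Wishart draws are generated by the Bartlett
construction and consumed as Cholesky factors of the precision: when β
approaches its lower bound the draws are numerically rank-deficient, and
assembling the matrix before re-deriving its determinant cancels
catastrophically, whereas the factor form is exact. Rare non-positive
posterior scale matrices are jittered in proportion to their trace and
resampled, with a logged warning.

Behaviour on the default synthetic population (40 cells): posterior-median
RMSE ~0.006 log-units, 90% credible-interval coverage within the binomial
band around nominal, MH acceptance ~0.30, full run ≈ 45 s on one CPU. The
posterior on the number of occupied components concentrates on the two
generating subpopulations but keeps genuine mass on one extra transient
singleton (a property of the Dirichlet-process prior with α ~ Gamma(1,1),
not a sampler defect), so the modal count can occasionally report 3.

## Bulk assays

One-phase decay `y(t) = (Y0 − plateau)e^{−t/Tau} + plateau` is fit by
nonlinear least squares; initialization takes Y0 and the plateau from the
series edges and Tau from the log-linear slope of the plateau-subtracted
early decay. Parameter SEs come from the Jacobian at the optimum;
across-replicate spread is reported separately when replicates exist.
The plateau is free by default (appropriate for fluorescence series with
residual background); `fix_plateau=0` matches assays that decay to complete
depletion, such as extracellular glucose consumption. For Tau-recovery
experiments the matched model (fixed zero plateau, known noise weights) is
used; with the plateau left free the three-parameter fit on 10 points has a
Tau sampling SD of ~4% at 5% noise, an estimation-theoretic limit worth
knowing when comparing conditions.

The colorimetric pipeline blank-subtracts the glucose standards, fits a
least-squares line through (amount, absorbance), inverts sample absorbances
to amounts, and reports `C = S_a / S_v` (nmole/µL).

## Summary statistics

CV is `100 · sample SD / mean` with the n−1 denominator (the source does not
state one). Pearson correlation uses the t-transform two-sided p-value;
group comparisons use the unpaired two-tailed Welch t-test with
Satterthwaite degrees of freedom. Background-subtracted values may be
negative at low signal; they are kept (clipping would bias means upward)
and flagged. Percent-of-baseline is `100 · new/old`: this ratio convention
is the only arithmetic consistent with both printed condition pairs
(740→1072 reported as 145%, 1072→1714 as 160%) even though the comparisons
are worded as increases; the discrepancy is documented rather than
resolved. Steady-state means are taken at the sample nearest t = 900 s
(within half a frame interval), averaged across cells with SEM.

## Problem sizes

Default test and acceptance runs use the study-scale experiment — 40 cells,
106 frames, 5000 Gibbs sweeps — plus 100-instance forward-model oracle
comparisons, 200-replicate decay recoveries, and 2000-sweep CRP checks;
the whole suite completes in about a minute on one CPU, so no scaled-down
surrogate problems are needed.

## Known limitations

- Uptake is first order in `[gluc]_ex`; transporter saturation
  (Michaelis–Menten) is out of scope, as is a growth/dilution term.
- One shared extracellular profile per experiment; per-cell channel
  profiles are not modelled.
- Convergence is reported via acceptance rates and draw summaries; no
  automated convergence gating.
- The occupied-component count inherits the usual Dirichlet-process
  sensitivity to α's prior; comparisons across datasets should use the full
  posterior over the count, not only its mode.
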