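# Methods

## The chamber model

The cuvette (interior 8 × 40 × 0.5 mm, V = 0.16 mL) is modelled as a
single well-mixed compartment (CSTR): inflow at volumetric rate Q
instantly mixes with the chamber content, so a change of inflow
concentration relaxes exponentially with time constant V/Q. This choice
is anchored on the measured fluid-replacement times: 99% replacement of
a 0.16 mL chamber takes 13.0 min at 3.4 mL/h and 7.4 min at 6 mL/h
under CSTR mixing, matching the ~12 and ~6 min observed when switching
liquids, whereas plug flow would predict 2.8 and 1.6 min. An optional
transport delay (default 0) shifts the inflow schedule to represent
tubing dead volume; it is a knob, not a calibrated value.

The ligand is split at the inlet into an immunoreactive pool
L_r = IRF · C_in and an inert pool L_i = (1 − IRF) · C_in. Both carry
activity and contribute to the solution signal; only L_r binds. With
R_tot = N_ar/N_A the total antigen amount (mol) and B the bound amount
(mol):

    dB/dt   = k_on · L_r · (R_tot − B) − k_off · B
    dL_r/dt = (Q/V) · (L_r,in − L_r) − (1/V) · dB/dt
    dL_i/dt = (Q/V) · (L_i,in − L_i)

Depletion of free ligand by binding (the −dB/dt/V term) is included; at
the standard operating point it transiently consumes up to ~10% of the
inflow, which is why the solution-signal reference from a cell-free run
slightly over-subtracts during uptake and why the fit folds the
subtraction into the forward model instead.

The detector response is

    true_cps = eff_bound · A_bound
             + eff_solution · C_solution · (1 + wall_fraction)
             + background

with A_bound (kBq) and C_solution (kBq/mL) obtained from B and
(L_r + L_i) through the specific activity, scaled by exp(−λt) when a
radionuclide half-life is configured. Decay is off by default: for
¹²⁵I-length runs it is below 0.15% over 3 h; it exists because the
motivating application is short-lived α-emitters (²¹¹At, t½ = 7.2 h;
²¹³Bi, t½ = 45.6 min). Specific activity is defined at t = 0; decay
scales activity-derived signals, never molar amounts. Dead time is
non-paralyzable, observed = true/(1 + true·τ); the default calibration
helper solves a 2.5% loss at 1600 cps, giving τ = 1.603 × 10⁻⁵ s.
Wall adsorption is a static multiplicative factor on the solution
signal (default 0; calibrated below 2% on the prototype), not a kinetic
compartment, because only a steady-state magnitude is available.

### Numerics

The state vector is augmented with cumulative inflow/outflow moles and
cumulative true/observed/solution-derived counts, so mole balance and
channel-integrated count expectations are exact to solver accuracy —
including channels containing an inflow switch; no midpoint shortcut is
used anywhere. Two engines share one right-hand side:

- an adaptive LSODA path (rtol 1e-8, atol 1e-18 by default, both
  exposed) integrated piecewise between inflow discontinuities, used
  for trajectory export and as the numerical reference;
- a compiled fixed-step RK4 path (default dt = 1 s) used for the
  thousands of forward solves a fit performs (~2 ms per solve). The
  fastest model timescale is the mixing constant V/Q ≈ 100–180 s, so a
  1 s step is ~100× below it and the two engines agree to ~1e-7
  relative; the test suite enforces 1e-6 and additionally checks the
  adaptive path against closed forms (CSTR step response,
  pseudo-first-order binding, equilibrium law B_eq = R_tot·L/(L + K_d))
  and an independent explicit-Euler integration at 10 ms steps.

Tiny negative states far below solver tolerance are clipped to zero; a
violation beyond 1e-6 of the natural scale raises a model error rather
than being silently repaired.

## Synthetic data

Counts per channel are Poisson with mean equal to the exact integral of
the observed rate (dead time and background included) over the channel
— the physical noise model for γ-counting; no Gaussian electronics
noise is added, consistent with the low-noise traces the instrument
produces. Dead time is applied to the instantaneous rate before
integration, an approximation that is excellent at ≤2.5% losses.
Defaults are the prototype's standard operating point: 3.2 mL/h flow,
0.5 µg/mL antibody (148 kDa), 100 kBq/µg (mid-range of the 40–200 used),
IRF 0.95 (mid-range of the measured 0.85–0.99), 1-min channels, 3 h
uptake + 2 h washout, 10⁶ seeded cells, efficiencies 65 cps/kBq and
5.1 cps per kBq/mL. The batch sampler draws k_on and k_off log-uniform
over the ranges the 17 reproducibility runs spanned
(3.18–7.94 × 10⁴ M⁻¹s⁻¹ and 0.11–4.2 × 10⁻⁵ s⁻¹) and N_ar uniform over
0.3–2.2 × 10¹². What the generator does *not* emulate: cell detachment,
coverslip placement error, antigen-expression drift between passages,
antibody internalization and antigen recycling, and any mismatch
between the CSTR mixing model and the real chamber hydrodynamics.
Recovery results on synthetic data therefore demonstrate estimator
correctness under the model, not robustness to these real-data effects.

## Fitting

The loss is least squares between measured counts and the forward
model's expected channel counts over (log₁₀ k_on, log₁₀ k_off,
log₁₀ N_ar); linear-space optimization is available and agrees to 1e-3
on well-posed instances. The default weighting is Poisson
(variance = model-predicted counts), which is the χ² statistic for
counting data; an unweighted mode on net counts is provided for
fidelity to analyses that fit background-subtracted curves directly.
Because the solution contribution is part of the forward model, the
subtraction is folded into the fit — algebraically equivalent to
fitting net counts, but it keeps the Poisson weights honest.
Optimization is trust-region-reflective least squares from 8 seeded
starts (one at the geometric centre of the bounds box, the rest
log-uniform); bounds default to k_on ∈ [10³, 10⁷] M⁻¹s⁻¹,
k_off ∈ [10⁻⁷, 10⁻³] s⁻¹, N_ar ∈ [10¹⁰, 10¹³], generously bracketing
all observed values. Equal-loss ties break toward the smallest k_off
(parsimony toward irreversible binding on short timescales), and a
result at the lower k_off bound is flagged `koff_at_bound`.

### k_off identifiability

On uptake-only data the observable kinetics are, to first order, the
initial slope k_on·L·R_tot and the relaxation rate
k_obs = k_on·L + k_off: k_off trades exactly against k_on and N_ar
along a flat ridge, and only the washout phase (or an uptake comparable
to 1/k_off, days at these rate constants) breaks it. Two rules decide:

1. **No washout and uptake below a minimum** (default 10⁵ s ≈ 1/k_off
   for the fallback value): k_off is declared non-identifiable outright.
   In practice this covers every no-washout acquisition, mirroring how
   prematurely terminated runs were handled on the instrument.
2. **Profile flatness** otherwise: the loss is profiled over a log grid
   of k_off (re-optimizing k_on and N_ar at each point, warm-started
   from the best fit); if the region within 1% of the minimum spans two
   or more contiguous decades, k_off is non-identifiable. The span, not
   the full-bounds range, is the criterion: even on hopeless data the
   loss always rises near the 10⁻³ s⁻¹ bound (dissociation that fast
   would visibly reshape the uptake curve), so demanding flatness
   across the entire box would never trigger.

Non-identifiable fits are re-run with k_off frozen at a fallback value
— default 0.45 × 10⁻⁵ s⁻¹, the median of the runs where it could be
estimated — and flagged `koff_imputed`; batch statistics for k_off then
exclude them by default (including seven imputed 0.45 values among ten
estimates would drag the mean toward the fallback; the policy is
explicit and switchable).

### Dead-time sensitivity

The pipeline's dead-time correction (`correct_dead_time_counts`)
inverts the non-paralyzable model on per-channel mean rates and is off
by default. The dedicated sensitivity experiment
(`dead_time_sensitivity`) quantifies whether ignoring dead time matters
for k_on, and the form of the correction matters for what it reports:

- Correcting the **net cell-bound curve by the single loss figure
  measured at the peak rate** (loss = peak observed rate × τ, exactly
  the non-paralyzable loss fraction) — the way a one-number dead-time
  calibration is applied to an uptake series in practice — rescales the
  bound amplitude, which N_ar absorbs, and moves k_on by only ~0.3% at
  a 2.5%-loss peak. This is the primary number the experiment reports,
  and it reproduces the sub-1% sensitivity measured on the instrument.
- A **full per-channel inversion of the total counts** additionally
  reweights the rising part of the curve relative to the plateau
  (losses are rate-dependent), shifting the apparent relaxation rate;
  it moves k_on by ~3% under the same conditions and is reported
  alongside as a diagnostic.

Both numbers are computed on fits whose k_off is imputed identically
(uptake-only acquisition), so the comparison is not contaminated by the
k_on/k_off ridge.

## Batch statistics and ancillary assays

Summaries use the sample standard deviation (n − 1), CV = 100·SD/mean,
and the midpoint-of-middle-two median. Display scalings follow the
assay-table conventions (k_on × 10³ M⁻¹s⁻¹ to one decimal, k_off × 10⁻⁵
s⁻¹ and B_max × 10⁶ per cell to two decimals, CV as whole percent)
while all stored values stay SI. B_max per cell is N_ar divided by the
number of *seeded* cells — an apparent value, since the cells actually
present and their antigen expression are not measured per run.

The immunoreactive fraction is estimated by the standard linear
extrapolation: total/bound activity against inverse antigen excess,
IRF = 1/intercept at infinite excess, clipped to (0, 1] with an
out-of-range flag and a hard error for non-positive intercepts. The
saturation assay converts plateau cell-bound activity to molecules per
cell through the specific activity and molar mass.

## Problem sizes and reproducibility

Every stochastic component (generator, batch sub-seeding via a seed
sequence, multistart draws) is driven by explicit integer seeds, and
pipeline outputs are pure functions of (inputs, configuration, seed,
version); the CLI writes a manifest sidecar per output recording all of
them. The recovery studies in the test suite use 17 assays at the
standard operating point and a 50-replicate bias check at reduced
multistart count (2 starts, identifiability check off), sizes chosen to
exercise the estimator across the sampled parameter ranges at
comfortable runtimes; a full single fit (8 starts plus profile) takes a
few seconds on one core.

## Known limitations

- The CSTR mixing assumption is validated only through replacement
  times; real chamber hydrodynamics (laminar boundary layers over the
  cell monolayer, diffusion to the surface) are not modelled, and no
  spatial transport model is provided.
- Binding is monovalent 1:1; no bivalent avidity, internalization, or
  antigen recycling.
- Detector efficiencies are fixed calibration inputs, never co-fitted.
- The k_off fallback value is a population median, not an estimate; all
  downstream statistics must treat imputed values accordingly (the
  summary module does).
- Dead-time correction on channel means is exact only for rates
  constant within a channel; at 1-min channels and these kinetics the
  residual error is below 2 × 10⁻⁴ relative.
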