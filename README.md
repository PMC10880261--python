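# flowbind

Kinetic analysis of real-time radioligand binding to living adherent
cells in a flow-through cuvette.

## The problem

Radioligands for tumor targeting (for example a radiolabelled antibody
such as ¹²⁵I-trastuzumab binding HER2 on SKOV-3 ovarian-carcinoma cells)
are characterized by the association rate constant *k*ₒₙ (M⁻¹ s⁻¹), the
dissociation rate constant *k*ₒff (s⁻¹), and the number of available
binding sites. A real-time assay for these quantities grows the cells as
a monolayer on a coverslip inside a shallow flow-through cuvette
(0.16 mL), perfuses radioligand solution at a few mL/h, and records the
chamber's γ-activity in one-minute channels with a NaI detector mounted
underneath. The count rate combines coverslip-bound activity and the
activity of the chamber liquid; switching the inflow to blank medium
starts a washout phase in which dissociation dominates.

`flowbind` provides, for this class of instrument:

- a **mechanistic forward model** of the chamber — a well-mixed (CSTR)
  compartment with bimolecular binding, ligand depletion, an
  immunoreactive and an inert ligand pool, radioactive decay, and the
  detector response including non-paralyzable dead time:

  dB/dt = *k*ₒₙ·L·(R_tot − B) − *k*ₒff·B,
  dL/dt = (Q/V)·(L_in − L) − (1/V)·dB/dt

- a **synthetic data generator** drawing Poisson counts from exact
  channel-integrated rate expectations, with known ground truth;
- a **preprocessing stage** converting raw curves to net cell-bound
  counts (dead-time inversion, solution/background/wall subtraction);
- an **iterative least-squares fitter** recovering (*k*ₒₙ, *k*ₒff,
  N_ar) by seeded multistart optimization in log-space, with a
  profile-based identifiability check that freezes *k*ₒff at a fallback
  median when an acquisition terminated before washout;
- **batch statistics** (mean/SD/CV/median per parameter, with imputed
  *k*ₒff excluded from its statistics), the Lindmo immunoreactive-fraction
  extrapolation, and saturation-assay antigens-per-cell arithmetic;
- a **command-line interface** (`flowbind simulate | generate | fit |
  summarize | irf`) over TOML configurations and CSV curves.

## Worked example

```python
import flowbind as fb

config = fb.AssayConfig()          # 3.2 mL/h, 0.16 mL, 0.5 ug/mL @ 100 kBq/ug, 3 h + 2 h
calib = fb.DetectorCalib()         # 65 cps/kBq bound, 5.1 cps per kBq/mL solution
truth = fb.KineticParams(k_on=4.5e4, k_off=0.45e-5, n_antigens_total=1.1e12)

curve = fb.generate_curve(config, calib, truth, seed=7)
print(f"peak observed rate: {curve.counts.max() / 60:.0f} cps")

result = fb.fit(curve, config, calib, fb.FitOptions(seed=1))
print(f"k_on  = {result.k_on:.3g} M^-1 s^-1")
print(f"k_off = {result.k_off:.3g} s^-1 (imputed: {result.koff_imputed})")
print(f"N_ar  = {result.n_ar:.3g} ({result.b_max_per_cell:.3g} antigens/cell)")
```

prints

```
peak observed rate: 1576 cps
k_on  = 4.5e+04 M^-1 s^-1
k_off = 4.46e-06 s^-1 (imputed: False)
N_ar  = 1.1e+12 (1.1e+06 antigens/cell)
```

i.e. on a typical 3 h uptake + 2 h washout run the ~1600 cps-peak
Poisson trace returns all three parameters within a percent of the
ground truth: the association constant, the dissociation constant
(estimated, not imputed, because the washout was recorded), and the
total antigen number — 1.1 × 10⁶ antigens per cell for the 10⁶ seeded
cells. A batch of fitted runs is condensed to the assay table
conventions with
`fb.format_summary(fb.summarize_batch(results))`, which prints
mean/SD/CV/median per parameter in display units (*k*ₒₙ × 10³,
*k*ₒff × 10⁻⁵, B_max × 10⁶), computing *k*ₒff statistics over
non-imputed fits only.

The same pipeline from the shell:

```sh
flowbind generate --config assay.toml --seed 7 --out curve.csv
flowbind fit --config assay.toml --curve curve.csv --out fit.json
```

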