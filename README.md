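# cdphotostab

Quantitative analysis of cyclodextrin-assisted photostabilization of a
photolabile drug — built around the 5-fluorouracil (5-FU) / α-, β-, γ-
cyclodextrin (CD) system.

5-FU degrades under UV light by first-order kinetics.  Entrapment in the
hydrophobic CD cavity slows the photolysis: the apparent rate constant
falls linearly with host concentration,

```
kobs = k0 − k2·[CD]
```

where `k0` (min⁻¹) is the CD-free rate and `k2` (M⁻¹·min⁻¹), the
second-order photochemical interaction constant, measures the strength of
the stabilization.  The package implements the full workflow a
formulation-photochemistry group needs around that model:

* **kinetics** — log-linear first-order fits of photolysis time courses,
  the secondary `kobs` vs `[CD]` regression giving `k2`, assembly of
  `kobs`–pH profiles and location of the most photostable pH;
* **photophysics** — Stern–Volmer quenching (`F0/F = 1 + Ksv[Q]`), the
  double-logarithmic binding plot
  (`log₁₀[(F0−F)/F] = log₁₀K + n·log₁₀[Q]`), percent fluorescence loss and
  entrapment efficiency;
* **stoichiometry** — Job's continuous-variation peak (maximum at mole
  fraction 0.5 ⇒ 1:1 complex) and the conductometric breakpoint by
  exhaustive two-segment piecewise-linear least squares;
* **speciation** — Henderson–Hasselbalch neutral/anion fractions
  (pKa 8.0) annotating the pH profile;
* **actinometry** — photon-flux bookkeeping and quantum yields
  `Φ = (k·C·V/60) / (R·Q/N_A)`;
* **assay validation** — ICH-style calibration statistics: linearity with
  standard errors, `LOD = 3.3σ/S`, `LOQ = 10σ/S`, accuracy and precision;
* **synthetic data** — a seeded generator for every series type, exact
  closed-form at zero noise, so the entire pipeline is testable offline.

The published result tables of the underlying study (the `kobs` grid, the
quenching/binding constants, the calibration statistics) ship in
`cdphotostab.datasets` both as regression inputs and as the `paper2025`
generating bundle for the synthetic series.

## Worked example

Recover the interaction constant for γ-CD at pH 6.0 from the published
rate-constant grid:

```python
from cdphotostab import datasets, fit_interaction, stabilization_percent, species_fractions

df = datasets.kobs_table()
grp = df[(df.ph == 6.0) & (df.cd_type == "gamma")]
fit = fit_interaction(list(zip(grp.cd_conc_M, grp.kobs_per_min)), 6.0, "gamma")
print(f"k2(gamma, pH 6)  = {fit.k2:.2f} M^-1 min^-1   (r^2 = {fit.r_squared:.4f})")
print(f"k(0 CD) extrapolated = {fit.k_at_zero_cd*1e3:.2f} x10^-3 min^-1 "
      f"(measured k0 = {datasets.K0_BY_PH[6.0]*1e3:.2f})")
print(f"stabilization at 1.25 mM = "
      f"{stabilization_percent(datasets.K0_BY_PH[6.0], grp.kobs_per_min.iloc[-1]):.1f}%")
frac = species_fractions(12.0, 8.0)
print(f"anion fraction at pH 12 (pKa 8) = {100*frac.f_anion:.2f}%")
```

prints

```
k2(gamma, pH 6)  = 1.04 M^-1 min^-1   (r^2 = 0.9966)
k(0 CD) extrapolated = 2.16 x10^-3 min^-1 (measured k0 = 2.11)
stabilization at 1.25 mM = 59.7%
anion fraction at pH 12 (pKa 8) = 99.99%
```

γ-CD at 1.25 mM roughly halves the photodegradation rate at the stability
optimum (pH 6), and the zero-CD extrapolation of the secondary regression
agrees with the independently measured `k0` — the internal consistency
check of the linear stabilization model.

## Command line

`cdphotostab` exposes one subcommand per stage (`simulate`,
`fit-kinetics`, `interaction`, `profile`, `quench`, `bind`, `entrap`,
`jobplot`, `conduct`, `validate`, `qy`, `run-all`); all interchange is
plain CSV with documented headers (see `cdphotostab.io`).  A full
synthetic run:

```sh
cdphotostab run-all --outdir out --seed 42
```

writes `rate_table.csv`, `interaction_table.csv`, `ph_profile.csv`,
`quenching_summary.csv`, `stoichiometry.csv`, `validation_report.csv`, a
`run.log` (seed, versions and every data-consistency flag raised) and a
`MANIFEST`.

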