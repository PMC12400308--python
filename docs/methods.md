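# Methods

## Models and procedures

**First-order photolysis.** A time course of remaining drug is fitted by
ordinary least squares of `ln(response)` on time; `kobs = −slope`.  The fit
is unweighted and linear rather than a nonlinear exponential fit: the
published rate constants were derived from "linear curves" in log space,
and the secondary-regression reproduction (below) validates the unweighted
convention.  `se_k` is the standard OLS slope error.  A constant series is
treated as an exact zero-slope line (`k = 0`, `se_k = 0`, `r² = 1`) rather
than propagating the undefined correlation of a zero-variance response.

**Secondary regression.** For each (pH, CD) cell the five `(cd_conc,
kobs)` pairs are fitted by OLS; `k2 = −slope` and the intercept is the
extrapolated zero-CD rate.  Re-fitting the published 11 pH × 3 CD × 5
concentration grid reproduces all 33 printed `k2` values within
±0.02 M⁻¹·min⁻¹ and the range extremes (0.49, 1.47, 2.14) exactly at two
decimals, which is the package's central worked example.  Values are kept
at full precision; two-decimal rounding is display-only.

**pH profile.** Rate fits are keyed by (pH, cd_type, cd_conc); exact
duplicates merge, conflicting duplicates raise, missing cells stay absent
(no imputation).  The minimum-rate pH is the grid argmin; ties resolve to
the lowest pH and are flagged.  No decomposition of the U-shaped profile
into specific/general acid–base catalytic terms is attempted — the
underlying study discusses the shape qualitatively only.

**Quenching and binding.** Stern–Volmer is OLS of `F0/F` on `[Q]` with a
*free* intercept; the model value is 1 and a deviation beyond 0.1 is
logged as a diagnostic (static vs dynamic quenching is out of scope).  The
binding fit is OLS of `log₁₀((F0−F)/F)` on `log₁₀[Q]` — base-10, the
convention of the double-log plot; `n = slope`, `K = 10^intercept`.  At
`n = 1` the two treatments coincide, which the tests assert.  Entrapment
efficiency `100(F0−F_free)/F0` and percent fluorescence loss
`100(F0−F)/F0` share their arithmetic but answer different questions (how
much drug is inside the cavity vs how much signal complexation removes),
so they are distinct operations with distinct validation.

**Job's method.** The 1:1 continuous-variation signal is modeled by the
exact equilibrium: at host fraction `x` and total concentration `T`
(1.00 × 10⁻⁴ M), the complex concentration is the smaller root of
`c² − c(H + G + 1/K) + HG = 0` with `H = xT`, `G = (1−x)T`.  The peak
locator takes the grid argmax, refines it by the vertex of the parabola
through the three points around an interior maximum, and converts the peak
fraction to a ratio as `round(x/(1−x)) : 1` (0.5 → "1 : 1").  A flat
series has no peak and is rejected.

**Conductometric breakpoint.** Continuous two-segment piecewise-linear
least squares with a hinge basis `(1, x, max(0, x−bp))`, exhaustively
searched over every interior data point leaving ≥ 3 points per segment;
ties go to the lower concentration.  Continuity is enforced because the
experimental curve is a single "sharp curve", not two disjoint lines.  A
break is reported as not significant when the two-segment fit improves the
single-line SSE by less than 20% — a logged heuristic, not a hypothesis
test.  The published claim that the break (2.00 mM) marks equimolarity
with the 0.2 mM drug solution is internally inconsistent; the pipeline
reports the empirical breakpoint and logs the note without adjudicating.

**Speciation.** Single ionisation (N1–H, pKa 8.0), Henderson–Hasselbalch;
no cationic species (the drug has no basic centre) and the second uracil
ionisation is ignored, matching the two-species treatment of the study.
The "0.0001% cationic at pH 2" figure in the source text is read as the
anion fraction at pH 2, which the formula reproduces.

**Quantum yield.** `Φ = (k/60 · C · V) / (R · Q/N_A)` — initial
degradation rate over absorbed photon flux, the standard photochemical
definition.  `R` is the ratio of absorbed-band emission areas (254, 313
nm) to the total over the five mercury bands.  The band areas behind the
published Φ column (0.030–0.095) were never printed and the source's
defining equations are unreadable images, so that column is explicitly not
reproduced; Φ is instead verified by its defining properties (hand-checked
arithmetic chain, invariance under common area rescaling, linearity in k,
C, V and inverse linearity in Q, R).  The quoted lamp intensity
"9.10 einstein s⁻¹" is dimensionally inconsistent with 5.50 × 10¹⁸
quanta s⁻¹ unless a 10⁻⁶ factor is implied; the conversion reports
9.13 × 10⁻⁶ einstein s⁻¹ and the pipeline logs the discrepancy.

**Assay validation.** Linearity by OLS with textbook standard errors
(cross-checked against the closed-form Σ formulas to 1e-12 relative in the
tests); `LOD = 3.3σ/S`, `LOQ = 10σ/S` with σ the *standard deviation of
the intercept* — the only reading under which the published α- and γ-CD
limits are reproduced at three significant figures.  With replicate
calibration curves σ is the sample SD of the per-curve intercepts;
otherwise it falls back to the OLS intercept standard error.  Sample
(n−1) standard deviations throughout.  The published β-CD intercept SD
(0.16 × 10⁴) cannot reproduce the published β-CD LOD/LOQ under any
standard formula (1.06 × 10⁴ would — likely a transposition); the checker
flags it and never substitutes a corrected value.  The published α-CD LOQ
(8.40 × 10⁻⁶) similarly disagrees with 10σ/S (8.04 × 10⁻⁶) and is flagged.

## Synthetic data

The generator emulates each series with its assumed statistical structure:
exponential decay with `kobs = k0 − k2[CD]` (validated positive for every
configured combination), hyperbolic quenching, power-law binding, the
exact 1:1 Job equilibrium, two-segment conductivity and a straight
calibration line.  Response noise is multiplicative lognormal with unit
mean — spectroscopic and chromatographic signals scale with the measurand
— except the calibration generator, which adds Gaussian detector noise of
fixed SD so that the intercept-SD → LOD chain is exercised on its own
terms.  The study reports no replicate counts or measurement error for the
kinetic runs, so the default noise (2% CV) is a convention chosen as
typical assay-level scatter, not a published value; the conductometric
tests use 0.5%, reflecting the much higher precision of a conductivity
meter.  Sampling times default to six uniform points over two half-lives
("appropriate intervals" is all the study states).

Seeding: each series type draws from its own `numpy` `SeedSequence`-derived
stream keyed by (seed, series-type code, CRC of the condition label), so a
fixed seed regenerates every series bit-identically and adding one series
never perturbs another.  At `noise_cv = 0` every generator is the exact
closed-form model and every downstream fit recovers its generating
parameters to machine precision — the backbone of the round-trip tests.

What the generator does **not** emulate: full UV spectra or chromatograms
(responses are scalar), buffer-catalysis structure in the rate–pH profile,
temperature effects, drift or heteroscedastic detector behaviour.  Passing
round-trip tests therefore demonstrate correctness of the estimators under
the assumed models, not robustness to real-data pathologies.

## Numerical choices

* OLS everywhere via `scipy.stats.linregress`; degenerate zero-variance
  responses short-circuit to the exact constant fit.
* The Job quadratic uses the smaller root (the physical branch, bounded by
  `min(H, G)`); the parabola refinement falls back to the grid maximum when
  the three points are collinear or the vertex leaves the bracket.
* Breakpoint search is exhaustive (the candidate set is the data grid), so
  the algorithm is its own brute-force oracle; the SSE comparison uses a
  1e-15 tie guard to keep the lower-concentration convention deterministic.
* Concentrations are molar in all files and APIs; display scalings (×10³,
  ×10⁵) are confined to report rendering.
* Noisy quenching responses are clipped at F0 so that generated series
  always satisfy the 0 < F ≤ F0 invariant; at the default noise level the
  clip is never active for the published constants.

## Problem sizes

The test suite and the acceptance script run on the scale of the study
itself: 5-point titrations, 6-point time courses, 11-point Job grids,
16-point conductometric curves, the 11 × 3 × 5 rate grid, and 200-seed
repetitions for the coverage checks — a few seconds end to end.

## Known limitations

* The published Φ column and the raw fluorescence tables live only in
  unpublished supplementary material; the corresponding checks are
  property-based rather than value reproductions.
* The "no significant break" threshold (20% SSE improvement) and the
  Stern–Volmer intercept tolerance (0.1) are pragmatic diagnostics, not
  calibrated tests.
* Quantum-chemical and docking results of the source study are out of
  scope entirely.
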