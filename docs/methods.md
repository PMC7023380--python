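# Methods

## The assay

Coffee (200 mg ground beans) is extracted in 1.5 mL CDCl₃ with 1 % TMS,
shaken, filtered, and measured by 1D ¹H NMR at 400 MHz (zg30, 64 scans,
relaxation delay 30 s, TD 131072, SW ≈ 20.55 ppm, SI 262144, LB 0.30 Hz).
Five analytes are quantified from single characteristic resonance windows:

| analyte | window (ppm) | protons used | M (g/mol) | recalculation factor |
|---|---|---|---|---|
| 16-O-methylcafestol (OMC) | 3.125–3.185 | 3 (O-CH₃) | 330.46 | 1 |
| caffeine | 3.38–3.44 | 3 (N-CH₃) | 194.19 | **6** |
| kahweol | 5.85–5.925 | 1 | 314.42 | 1 |
| furfuryl alcohol | 7.39–7.411 | 1 | 98.10 | 1 |
| HMF | 9.67–9.69 | 1 (CHO) | 126.11 | 1 |

The proton counts are chemically motivated defaults for the integrated
patterns and are configurable; the window limits are the assay's fixed
constants. Quantification is external (PULCON-style): a proton-normalized
peak area `A/nH` is converted to molarity by a single per-instrument
*eretic factor* determined once against a quantification reference, then
to mg/L via the molar mass, and to mg/kg of coffee via the extraction
stoichiometry (1.5 mL / 0.200 kg·10⁻³ = 7.5 mg·kg⁻¹ per mg·L⁻¹).
Caffeine dissolves only partially in CDCl₃; the empirical factor 6
(established against an HPLC reference method) rescales the solution
concentration to the true content. The eretic factor is the assay's single
calibration degree of freedom; in this package the simulator's device
constant and the quantifier's factor are reciprocal by construction, which
is what a properly calibrated instrument provides.

## Spectral processing

* **FID convention.** Complex FID of TD/2 points, dwell time 1/SW, so
  AQ = TD/(2·SW) — 7.97 s at the printed TD and SW.
* **Apodization.** Multiplication by `exp(−π·LB·t)` adds exactly LB Hz to
  every Lorentzian FWHM.
* **Transform.** The first point is halved (trapezoid-consistent DC
  handling), the FFT is scaled by the dwell time so spectral areas match
  the continuous-transform areas of the time-domain model, and the axis is
  laid out descending with the Nyquist bin mapped to +SW/2. A one-sided
  decaying complex exponential of t = 0 amplitude *a* yields an absorption
  line of area *a*/2 (in Hz); the simulator's FID synthesis inverts that
  relation.
* **Phasing.** Zero/first order chosen to minimize integrated squared
  negative intensity (coarse zero-order grid, Nelder–Mead refinement).
  This reproduces the *behaviour* of an instrument's automatic phasing,
  not any vendor's specific algorithm.
* **Baseline.** Asymmetric least squares (Whittaker smoothing, asymmetry
  p = 0.001, 20 reweighting iterations). The stiffness default
  λ = 0.3·(N/100)⁴ scales with the fourth power of the point count so the
  effective curvature scale is resolution-independent; it was chosen so
  that a linear baseline under an isolated line is removed with < 1 %
  area error while a constant offset is removed essentially exactly.

## Window integration and the OMC correction

`linefit` fits K Lorentzians (default K = 1; every window isolates one
pattern) plus a local linear baseline by bounded least squares and reports
the *analytic* Lorentzian area πhγ, which restores the tails the finite
window cuts off — at 1.3 Hz FWHM the narrow HMF window (8 Hz) holds only
~90 % of the line's area, so plain summation is structurally biased low.
The `sum` method (trapezoid with interpolated window-edge ordinates, so
the integral spans the window exactly) is retained as the brute-force
reference. Non-converged fits fall back to `sum` with a flag.

The fatty-acid background of roasted coffee inflates the OMC window. The
correction integrates the equal-width, analyte-free reference window
3.04–3.10 ppm and subtracts it from the OMC window total; any locally flat
interference cancels exactly because the windows have identical width
(0.06 ppm). For the line fit, the OMC "window total" is defined as
Lorentzian area **plus** the fitted local baseline's integral — in this
window the local baseline *is* the interference being subtracted.
Negative corrected areas clip to zero with a flag.

## Simulator

The simulator emulates the measurement, not the physics of extraction:

* analyte lines are pure Lorentzians (natural FWHM 1.0 Hz + LB) of area
  `k_device · c/(1000·M) · nH` — the exact model the eretic factor
  inverts; multiplets are not modelled because the windows integrate whole
  patterns anyway;
* caffeine contributes only `c × dissolved fraction` (default 1/6, the
  deficit the factor 6 corrects);
* the matrix interference is a hump near 2.9 ppm plus a locally flat
  shoulder spanning 3.0–3.21 ppm, so it loads both OMC-region windows
  equally to < 0.5 % — the property the correction relies on;
* noise is additive white Gaussian per point (`noise_sd`), plus an
  optional per-analyte proportional area jitter (`proportional_noise`)
  representing run-to-run measurement scatter;
* default desk-scale grid: TD 16384 / SI 65536 at the full spectral
  width. This keeps ≥ 5 points per linewidth and ≥ 30 points in the
  narrowest window while making a full 144-measurement factorial study
  simulate and quantify in seconds; the full-size TD/SI presets remain
  available.

The validation-study presets encode what the three matrices do to the
measurement: decaffeinated arabica is the well-behaved reference (7 %
proportional scatter), robusta extracts kahweol at 74 % and carries
strong interference, green coffee is the failing matrix (extraction
biases 1.37/0.54/1.88/0.93/1.07 for caffeine/OMC/kahweol/furfuryl
alcohol/HMF and 30 % scatter). Matrix native analyte contents are kept at
trace level: spike-recovery validation presupposes matrices whose own
content does not swamp the lowest spikes, and the reference matrix is
decaffeinated for exactly that reason. A 10-minute shake applies a 1 %
deficit — visible in raw numbers, below statistical significance, as a
ruggedness factor should be. The two device presets differ only in their
(calibrated-out) response constants and SW dialects, so the instrument
has no systematic effect on results.

What the simulator does **not** model: multiplet structure, ¹³C
satellites, field inhomogeneity and shimming, solvent suppression,
temperature drift, filtration losses, and real extraction kinetics.
Passing tests therefore demonstrate that the *data analysis* is correct
and unbiased under the stated signal model, not that the wet-lab assay
performs to specification on real beans.

## Validation statistics

* **DIN 32645 limits** (calibration-line method): with residual sd `s_y`,
  slope `b`, `n` points, mean spike `x̄`, `Q_x = Σ(xᵢ−x̄)²`,

      LOD = (s_y/b) · t(1−α; n−2) · √(1 + 1/n + x̄²/Q_x)

  for one future measurement, and the determination limit solves
  `LOQ = k·(s_y/b)·t·√(1 + 1/n + (LOQ−x̄)²/Q_x)` by fixed-point iteration.
  Defaults α = 0.01 (the norm's customary one-sided level) and k = 3
  (33 % relative uncertainty at the limit); both configurable. Limits are
  fitted on the lower working range (default 7.5–375 mg/kg, the five
  lowest calibration levels — the norm needs ≥ 5 points).
* **Recovery** is the mean of per-level blank-corrected recoveries,
  `100·(measured − matrix blank)/spiked`, averaged over design cells;
  specification 90–110 %. A median aggregation is available.
* **Precision** is the CV (sample sd / mean, %) of the pooled
  blank-corrected per-level recoveries of a matrix; specification < 15 %.
* **Ruggedness ANOVA**: main-effects linear model of per-cell mean
  recovery on device, coffee type and shaking time, type-II sums of
  squares, α = 0.05; interactions optional. On the balanced 12-cell
  design this leaves 7 residual df per analyte.

## Screening rules

Thresholds follow the printed guidance values and are strict: declared
100 % arabica is suspicious when OMC > 50 mg/kg (equality is consistent);
declared decaffeinated is out of spec when caffeine ≥ 1000 mg/kg (the
regulation says "< 1000"); an optional, default-off rule flags declared
100 % robusta with kahweol ≥ 300 mg/kg. Green-coffee results are capped
at "indicative only" because the matrix failed recovery and precision
specifications. Suspicious findings are labelled as requiring
confirmatory analysis (HPLC reference procedure); the package does not
implement the confirmation.

## Numerical and design choices

* Lorentzian line shape (not Gaussian/Voigt) for fitting and simulation:
  the physical limit shape of a well-shimmed liquid-state line, and the
  shape the exponential window preserves.
* A stochastic acceptance check on calibration linearity (5 % proportional
  noise, 10 levels) is evaluated as the mean R² per analyte across 20
  seeded runs: a single series has a ~2 % chance of dipping below 0.99
  under those very conditions, so the per-seed minimum is reported but
  not gated on.
* Degenerate inputs: two-point calibrations are flagged
  `under_determined`; constant spike designs, non-positive slopes,
  zero-mean CVs and empty windows raise typed errors; per-analyte and
  per-sample failures are isolated, never silently dropped.
* Carrier frequencies are not asserted, only derived from the SW
  dialects (8223.68 Hz / 20.5503 ppm and 8223.69 Hz / 20.5617 ppm) and
  carried as metadata.

## Known limitations

The line fit assumes one dominant Lorentzian per window; heavily
overlapped foreign signals inside a window would require raising K or
re-assigning windows. The JCAMP-DX reader covers plain (X++(Y..Y)) AFFN
tables only. The eretic factor must be supplied (or matched to the
simulator); the package does not implement the external quantification
reference measurement itself. Absolute detection limits depend on the
simulated noise level and are not comparable to any particular
instrument's values.
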