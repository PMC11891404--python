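# Methods

`nbtherm` analyses the equilibrium unfolding thermodynamics of small
single-domain proteins — it was written around a set of camelid nanobodies
raised against alanine:glyoxylate aminotransferase (NB-AGT-1, -2 and -6) —
from two kinds of experiment: thermal denaturation followed by differential
scanning calorimetry (DSC) and isothermal chemical denaturation by GdmHCl
followed by tryptophan fluorescence. The two routes are combined into a
protein stability curve ΔG(T).

Throughout, ΔG is the *unfolding* free energy (positive when the native
state is favored), temperatures are kelvin internally (I/O accepts °C and
converts with +273.15), energies are carried in cal·mol⁻¹ internally and
reported in kcal·mol⁻¹, and the gas constant is R = 1.987 cal·mol⁻¹·K⁻¹ —
the value conventional in protein calorimetry, kept exactly so published
tables are reproduced.

## Thermal denaturation (DSC)

The apparent molar heat capacity of a scan is modelled as

    Cp,app(T) = a + b·T + ΔHcal·ΔHVH / (R·T²) · K/(1+K)²
    K(T)      = exp[ −(ΔHVH/R)·(1/T − 1/Tm) ]

where `a + b·T` is the native-state baseline, ΔHcal the calorimetric
enthalpy (the area under the transition peak), ΔHVH the Van't Hoff enthalpy
governing the temperature dependence of the equilibrium constant K, and Tm
the temperature at which K = 1. The model does not force ΔHcal = ΔHVH;
their ratio is the standard cooperativity diagnostic (≈1 for two-state
unfolding). The form K/(1+K)² is the unique population factor whose
integral over the transition equals ΔHcal (since dfU/dT =
ΔHVH/(R·T²)·K/(1+K)² with fU = K/(1+K)); at Tm it equals exactly 1/4.

Fitting choices:

* **Post-transition exclusion.** The unfolded-state baseline is the part
  of a scan most distorted by irreversible processes at high temperature,
  so the default fit window ends where a first-pass estimate of the excess
  heat capacity falls below 5 % of its peak on the high-temperature side.
  The window is configurable; ΔCp is deliberately *not* a parameter of the
  scan model for the same reason.
* **Initial guesses** are reproducible without user input: baseline from
  the coolest 20 % of the grid, Tm at the detrended maximum, ΔHcal from
  the detrended area, ΔHVH from the two-state peak-height relation
  ΔHVH = 4·R·Tm²·Cp,max/ΔHcal.
* **Uncertainties** are curvature-based standard errors from the
  least-squares solver (`lmfit`/Levenberg–Marquardt).
* **Integration baseline** for model-free enthalpies (and hence
  reversibility) is the straight line joining the medians of the pre- and
  post-transition flat regions. The flat regions are found from a rough
  end-point detrend: the contiguous region where the detrended signal
  exceeds 2 % of its peak is treated as the transition and widened by half
  its width on each side (the exponential tails otherwise bias the
  medians); everything outside is "flat". This policy needs no model fit,
  so rescans without a clean transition are handled identically — a scan
  with no detectable peak reports zero enthalpy (with a warning), which
  lets a fully irreversible rescan report 0 % reversibility.
  Reversibility is 100·ΔHcal(rescan)/ΔHcal(upscan); values above 100 % are
  flagged, not clamped.
* **ΔG points within the transition** are −R·T·ln K evaluated from the
  *fitted* Tm and enthalpy at temperatures where the unfolded fraction
  lies in [0.05, 0.95] (K between 1/19 and 19, |ΔG| ≲ R·T·ln 19). Which
  enthalpy enters K is exposed as an option; the default is ΔHVH, the
  parameter the equilibrium constant is written with. Because
  −R·T·ln K = ΔHVH·(1 − T/Tm) exactly, these points are noiseless,
  perfectly linear functions of the fitted parameters — see the stability
  curve caveats below.
* **Scan-rate summary**: equilibrium unfolding must be scan-rate
  independent, so the OLS slope of Tm against scan rate above a threshold
  (default 0.5 K per K·min⁻¹) flags the equilibrium assumption as
  questionable.

No concentration normalization is performed; heat capacities are assumed
already molar. Multi-peak deconvolution and kinetic (Arrhenius /
Lumry–Eyring) models are out of scope.

## Chemical denaturation (GdmHCl, tryptophan fluorescence)

Emission spectra (320–380 nm, excitation 295 nm) are reduced to two
observables: the spectral center of mass SCM = Σ(I_λ·λ)/Σ(I_λ) over
320–380 nm, and the intensity ratio I365/I335 (linear interpolation for
off-grid wavelengths). Both red-shift/rise as buried tryptophans become
solvent-exposed; both are invariant to overall intensity scaling.

The denaturant dependence of each observable follows the two-state
linear-extrapolation model

    S([D]) = (S_N + m_N·[D])·(1 − fU) + (S_U + m_U·[D])·fU
    fU     = exp(x)/(1 + exp(x)),   x = m_eq·([D] − Cm)/(R·T)

with native/unfolded baselines (S, m) per observable and the cooperativity
m_eq (kcal·mol⁻¹·M⁻¹) and midpoint Cm (M) *shared* between observables in
a global fit per temperature. ΔG at zero denaturant is m_eq·Cm. fU = 1/2
exactly at [D] = Cm.

Fitting choices: per-observable residuals are divided by the median
absolute deviation of that observable's values before combining, so a
unitless ratio and an nm-scale SCM contribute comparably (the weighting is
unstated in the experimental literature this emulates; MAD weighting is
robust and reproducible). Initial Cm is where the min-max-normalized
signal crosses 0.5; initial m_eq is 3.3 kcal·mol⁻¹·M⁻¹, the
structure-energetics value for proteins of nanobody size. A fitted Cm
outside the sampled range is reported with an extrapolation warning; a
signal whose span is within a few median steps of its point-to-point
scatter raises "no transition detected". Blank subtraction is assumed done
upstream; denaturant concentrations are taken as given
(refractive-index correction out of scope); urea and ≥3-state models are
out of scope. Per-temperature values are reported with their mean ± SD
across temperatures; no temperature trend is modelled for m_eq.

## Stability curves and ΔCp

Two independent estimates of the unfolding heat-capacity change:

1. **Kirchhoff regression**: ΔCp = dΔH/dTm as the OLS slope of ΔHcal
   against Tm across mildly destabilizing conditions (low GdmHCl shifts Tm
   down a few kelvin). All points are pooled into one regression by
   default (one overall line across variants); a per-variant option
   exists.
2. **Gibbs–Helmholtz fit** of pooled ΔG(T) points — chemical points
   (T, m_eq·Cm) at 18–46 °C and DSC points near Tm:

       ΔG(T) = ΔH·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm))

   Tm is always held fixed (it is by far the best-determined parameter);
   either ΔH and ΔCp float, or ΔH is held at its calorimetric value and
   ΔCp floats. With Tm fixed the model is **linear in the free
   parameters**, so the fit is ordinary least squares with exact standard
   errors, passes through (Tm, 0) by construction, and is an exact
   interpolator of noise-free data. r² = 1 − SS_res/SS_tot over all points
   regardless of source. Points get equal weight by default
   (inverse-variance weights optional). A ΔCp standard error exceeding
   |ΔCp| is flagged "ΔCp not identifiable" and reported, not suppressed —
   near-Tm data alone cannot pin the curvature, which is exactly the
   published failure mode of the fixed-ΔH fit for the most stable variant.
   ΔG(Tm·exp(−ΔH/(Tm·ΔCp))) is the closed-form stability maximum,
   reported alongside ΔG at 4, 25 and 37 °C.

**A structural caveat worth knowing.** The DSC ΔG points are derived from
the fitted Van't Hoff model, so (a) they are exactly collinear with the ΔH
regressor of the Gibbs–Helmholtz model and carry no scatter — meaning
residual-based standard errors of a thermal-only fit are meaningless (the
package's tests therefore compare the ΔCp *design factor*
√[(XᵀX)⁻¹]_ΔCp, which is >2× larger without chemical points); and (b)
they ignore ΔCp inside the transition, departing from the true curve by
≈ ΔCp·(T−Tm)²/(2·Tm) — up to ~0.04 kcal·mol⁻¹ at the 5 % population edge.
Fitting the full default assembly therefore biases ΔCp by ~1.6 % and ΔH
by ~0.2 % even on noise-free data; the chemical-points-plus-(Tm, 0) route
recovers the generating curve to <0.1 %. This approximation is inherent
to the combined-fit method itself, not an implementation artifact.

## Synthetic data generator

No raw scans are publicly deposited for the study this package emulates,
so the generator is the acceptance surface: every input the pipeline
consumes is produced from a `GroundTruth` with known parameters.

* **Default ground truths** emulate the three characterized variants:
  Tm = 343.80/358.57/344.83 K, ΔHcal = 83.3/87.4/77.1, ΔHVH =
  92.3/105.9/94.1 kcal·mol⁻¹, reversibility 47/52/50 %, m_eq =
  3.1/4.4/4.1 kcal·mol⁻¹·M⁻¹, stability-curve ΔCp = 0.52/1.49/1.45
  kcal·mol⁻¹·K⁻¹. The generating stability curve uses ΔH = ΔHVH at Tm so
  that the thermal ΔG route (−RT·ln K) and the chemical route lie on the
  same curve, and Cm(T) = ΔG(T)/m_eq places the chemical midpoints on it;
  internal consistency is validated before a bundle is generated. The DSC
  native baseline (a = 1.5 kcal·mol⁻¹·K⁻¹, b = 0.005 kcal·mol⁻¹·K⁻²) is a
  typical molar baseline for a ~15 kDa protein.
* **DSC scans**: model curve plus Gaussian noise, default σ = 1 % of the
  upscan excess-Cp peak (no noise statistics are published; 1 % is
  realistic for a modern capillary DSC at 20 µM protein). Rescans scale
  the excess term by the reversibility fraction; noise stays at the
  upscan scale because instrument noise does not shrink with the signal.
  Default grid 293.15 K to Tm+30 K at 0.1 K.
* **Emission spectra**: native and unfolded template bands (skew-normal
  shapes; exact shape is arbitrary since only the derived sigmoids matter)
  mixed linearly by the model fU, a common linear amplitude drift in
  denaturant (default −2 %/M, emulating inner-filter/dilution drift — it
  cancels from both ratio observables), and Gaussian noise at 1 % of the
  series' maximum intensity. The unfolded template is built as a red band
  plus a narrow 335 nm component with coefficients solved so both
  templates share total intensity and 335 nm intensity. This matters:
  linear spectral mixing makes each observable follow a two-state sigmoid
  whose apparent midpoint is shifted by −R·T·ln(c)/m_eq, where c is the
  template intensity ratio at the relevant wavelengths (A_U/A_N for SCM,
  u335/n335 for the ratio); pinning both ratios to 1 makes both observables
  follow the generating model *exactly*, so noise-free bundles are fixed
  points of the analysis. Template SCMs land at ≈335 and ≈356 nm (red
  shift on unfolding).
* **Kirchhoff points**: Tm decreases linearly with denaturant (default
  6 K·M⁻¹ over 0–0.9 M) and ΔHcal follows the generating curve's ΔCp plus
  Gaussian scatter (default σ = 1 kcal·mol⁻¹), so the Kirchhoff and
  Gibbs–Helmholtz routes estimate the same quantity and any disagreement
  between them in an analysis is attributable to noise or model
  misspecification, not to the generator.
* **Determinism**: every generator draws from
  `default_rng([seed, crc32(product-label)])`, so identical ground truths
  give byte-identical files (numeric payloads are written with `%.17g`
  and read back with round-trip float parsing).

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: irreversible aggregation kinetics and
scan-rate-dependent Tm shifts (beyond a linear stub for testing the
diagnostic), non-Gaussian or correlated instrument noise, blank/baseline
drift in fluorescence beyond a linear amplitude term, curved DSC
baselines, and any intermediate-state (non-two-state) behavior.

## Problem sizes and numerical tolerances

Default problem sizes (also used by `scripts/acceptance.py`): DSC grids of
~800–950 points; 13-point denaturant grids at five temperatures; 10
Kirchhoff points; 25 thermal + 5 chemical points per stability curve;
recovery studies use 50 replicates (chemical) and 200 replicates
(Kirchhoff coverage, 100 points each). These match the scale of the
experiments emulated while keeping a full run in seconds.

Tolerances asserted by the test suite, each verified against an
independent route (quadrature oracles, 40-digit closed-form evaluations,
dense grid searches): noise-free DSC/chemical/stability fits recover
generating parameters to ≤0.01–0.1 %; the excess-Cp integral identity
holds to 0.1 % on a 0.01 K grid; at default noise, Tm is recovered within
0.05 K, enthalpies within 2 %, reversibility within 1 percentage point,
median Cm within 1 % and median m_eq within 5 %; the stability maximum
matches a 1 mK grid search within 0.01 K.

One statistical caveat: the "slope within 2·SE of truth in ≥95 % of
replicates" style of check for the Kirchhoff estimator has essentially no
Monte Carlo margin — the standardized slope error is exactly
t-distributed, so per-replicate 2·SE coverage is 95.17 % at 100 points
(capped at 95.45 % for any design), and a 200-replicate binomial draw
falls below 95 % roughly four times in ten for a *perfectly calibrated*
estimator. The suite therefore also asserts the stable properties —
unbiasedness and coverage within the binomial band of the analytic value.
The seed for all simulation studies was fixed up front.
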