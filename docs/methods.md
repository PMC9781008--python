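# Methods

This note documents the models, parameter choices and numerical
conventions behind `dnjquant`, and what the synthetic-data tests do and
do not demonstrate about real spectra.

## The calibration problem

A powdered mulberry-leaf product yields an ATR-FTIR absorbance spectrum
on a 750–4000 cm⁻¹ grid. The goal is a multivariate calibration that
maps the spectrum to the DNJ concentration (µg per g of dry material)
as a fast, non-destructive alternative to derivatization HPLC. The
workflow is: replicate averaging → baseline removal → SNV →
Kennard–Stone split → interval selection → PLS1 with autoscaling →
validation (LOO-CV, external test set, Y-randomization, applicability
domain).

## Synthetic spectra generator

The generator emulates the statistical structure the calibration
assumes, not instrument physics (no ATR penetration-depth or
interferogram modelling; that is out of scope by design).

**Signal model.** Each chemical component is a sum of Gaussian
(`h·exp(−ln2·((ν−c)/w)²)`) or Lorentzian (`h·w²/((ν−c)²+w²)`) bands with
center `c`, half-width-at-half-maximum `w` and height `h`. A product
spectrum is the Beer–Lambert mixture `Σ conc_k · pure_k(ν)`; each
replicate then receives a random polynomial baseline (order 2 by
default, coefficients Normal(0, 0.05 a.u.) on the grid mapped to
[−1, 1]), a multiplicative factor 1 + Normal(0, 0.02), and additive
Normal(0, noise_sd) noise. Additive-plus-multiplicative corruption is
exactly what SNV is designed to remove; wavelength-correlated noise is
deliberately not modelled.

**Grid.** 750–4000 cm⁻¹. The nominal instrument resolution of the
emulated study is 4 cm⁻¹, but the three fingerprint windows (each
~95 cm⁻¹ wide) must resolve to ~30 variables for the interval
arithmetic (window size 30, step 10) to be self-consistent, which
implies ~3.2 cm⁻¹ point spacing. The default `grid_spacing` is
therefore 3.2 cm⁻¹ (1016 points).

**Component library.** The default mixture was designed once, from the
known composition of dried mulberry leaf (15–30 % protein, 10–40 %
carbohydrate) and published band assignments, before any downstream
tuning:

| component | bands (cm⁻¹, HWHM, height/(µg/g)) | per-product concentration |
|---|---|---|
| DNJ (analyte) | 1150/20/8e-4, 1380/18/6e-4, 1650/22/5e-4 | uniform 10–1000 µg/g |
| polysaccharide | 1047/30, 1205/25, 935/20, 2920/60, 3350/150 | uniform 3.5–4.5·10⁵ |
| protein | 1541/25 (L), 1572/20 (L), 1655/30 | uniform 1.5–3.0·10⁵ |
| phenolics | 1600/25, 1280/30 | uniform 0.5–5·10⁴ |

The analyte bands sit inside the three fingerprint windows
(pyranose-ring C–O/C–C stretching at 1300–1000 cm⁻¹, C–H bending near
1410 cm⁻¹, N-H bending near 1650 cm⁻¹); the protein amide band at
1655 cm⁻¹ deliberately interferes with the third window, and the
dominant polysaccharide matrix sets the SNV normalization scale, so the
regression problem is multivariate rather than a univariate peak read.
Heights are scaled so each component contributes O(0.1–1) a.u.

**Concentration distribution.** Uniform per product over the configured
range. Real panels are bimodal (teas ~500–1000 µg/g, supplements
≲1 µg/g); uniform is the simplest structure that exercises regression
across the whole range and is the default for recovery tests.

**What passing tests show.** That the implementation recovers known
structure under the stated noise model. They do not show that a real
19-product panel would reach any particular R²: real spectra have
correlated matrix variation, water-vapour artefacts and inter-product
chemistry that no four-component mixture reproduces.

## Preprocessing

**WLS baseline.** Asymmetric iteratively-reweighted polynomial fit
(default order 2, max 100 iterations, weight-change tolerance 1e-6 in
relative L2 norm). Weights: 1 for points on/below the current baseline,
`exp(−r/σ)` above it, with σ the standard deviation of the *non-peak*
(non-positive) residuals — estimating σ from the points currently
treated as background keeps large peaks from inflating their own
tolerance and makes the recovered baseline essentially exact on
noiseless peaks-over-polynomial input.

**SNV** uses the n−1 standard deviation (stated so tests can be exact);
it is idempotent and removes any positive affine scaling.

**Ordering.** Replicates are averaged per product *before* the split so
that Kennard–Stone operates on product-level spectra and replicates can
never leak across the calibration/test boundary. Kennard–Stone
distances are computed on baseline-corrected + SNV spectra, before
autoscaling, because autoscaling parameters must be fitted on the
calibration subset which does not yet exist. Autoscaling is refit on
exactly the variables presented to each model (including every iPLS
candidate evaluation and every LOO fold).

## PLS1 and model selection

NIPALS with X-deflation (reference-quality and directly checkable
against textbook deflation and OLS at full rank; predictions match
scikit-learn's PLSRegression to machine precision in the cross-check
tests). The response is centered, not variance-scaled, so RMSEs are in
the units of the supplied y (µg/g here; if a normalized concentration
scale is supplied, RMSEs follow it).

**LV selection.** The smallest LV count whose LOO RMSE_CV lies within
1 % (relative) of the curve minimum. A fixed LV count (e.g. 6) can be
forced via `n_lv` to mirror an externally chosen model.

**iPLS.** Candidate windows of 30 consecutive variables every 10
variables, with a final window anchored at the grid end so coverage is
exact. Greedy forward selection on LOO RMSE_CV; the "auto" stop rule
accepts an addition only if it improves RMSE_CV by > 0.5 % relative.
The three printed fingerprint windows are shipped as a preset
(`ipls.DNJ_INTERVALS`) for reproducing a fixed final model; the search
path is not expected to return exactly those windows.

## Validation

**Y-randomization** (default 100 permutations): each permutation
shuffles y and refits the entire chain at fixed LV count. The real
R²_CV is compared with the permuted population via (a) one-sided
Wilcoxon signed-rank on the paired differences, (b) a one-sided sign
test on the same differences, and (c) the empirical randomization
p-value (1 + #{permuted ≥ real})/(n + 1). The construction of the three
named tests is a documented design choice; "randomization t-test" is
interpreted as the empirical permutation test. Pass criterion: p < 0.05.

**Applicability domain** (Williams plot): leverage
`h = 1/n + tᵀ(TᵀT)⁻¹t` in latent-score space, warning leverage
`h* = 3(k+1)/n`, studentized residuals `r/(s√(1−h))` for calibration
samples (s from n−k−1 degrees of freedom) and `r/s` for external
queries — query leverage is not bounded by 1, so the (1−h) correction
is omitted there, which is standard external-AD practice. Flags:
h > h* or |studentized residual| > 3. Query samples without reference
values get leverage-only flags.

## Wet-chemistry calculations

- LOD = 3.3 σ/S and LOQ = 10 σ/S with σ the standard deviation of ≥ 6
  blank responses (not regression residuals) and S the calibration
  slope; with levels in µg/mL the limits are reported in ng/mL. The
  LOQ/LOD ratio is exactly 10/3.3, so a LOQ recomputed from a *rounded*
  published LOD can differ in the last digit from the published LOQ
  (e.g. a printed LOD of 9.1 gives 27.58 vs a printed 27.7 obtained
  from the unrounded LOD); the three phenolic-assay values reproduce to
  two decimals.
- DPPH inhibition = 100·(A_blank − A_sample)/A_blank, clipped to
  [0, 100] with a flag — the blank-relative definition is the standard
  one and a documented choice.
- EC50 by linear interpolation between the two points bracketing 50 %
  on an isotonic-regularized (monotone non-decreasing) dose–response
  curve; a 4-parameter logistic fit is deliberately out of scope.
- RDI coverage = 100·(content·unit_mass·units_per_day/1000)/30 mg. The
  per-product unit mass is an input; it is not derivable from spectra.

## Problem sizes and determinism

The acceptance script and the stochastic tests use a 60-product
(triplicate) panel with additive noise at 0.5 % of the maximum mixture
absorbance — large enough for stable recovery statistics, small enough
to keep a full forward search plus a 100-permutation battery in tens of
seconds. All stochastic stages consume `numpy.random.default_rng`
generators seeded from explicit arguments; identical seeds give
bit-identical datasets, selections and reports.

## Known limitations

- No instrument-physics simulation; no smoothing/derivative or MSC
  preprocessing (the modelled workflow does not use them).
- The forward iPLS search is greedy; it can absorb matrix-correlated
  windows that carry analyte information only indirectly.
- Y-randomization's Wilcoxon/sign tests treat the permuted R²_CV values
  as independent paired observations; with heavy-tailed permutation
  distributions the empirical randomization p-value is the more
  trustworthy of the three.
- JCAMP-DX import is not implemented; spectra travel as delimited text.
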