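# Methods

## Reference ranges from aggregated study data

Published CMR normal-value compendia report per-study aggregates, not
individual measurements, so the package estimates reference ranges from
(n, mean, SD) triples.

**Single study.** The range is mean ± 2·SD.  Ranges are not meaningful for
cohorts under 40 subjects (the smallest n that supports a parametric 95%
interval under normality), so the pooling CLI rejects smaller studies by
default (`eligibility_filter`, `--min-n`); the threshold applies per sex
when ranges are sex-stratified.

**Pooled.** Study means are combined with a DerSimonian–Laird (DL)
random-effects model.  The within-study variance of each study mean is
taken as sd²/n; the between-study variance τ² is the DL moment estimator
truncated at zero.  The reference range targets *population* quantiles: an
individual drawn from a random study has variance σ²_within + τ², where
σ²_within is the df-weighted pooled within-study variance
Σ(nᵢ−1)sdᵢ²/Σ(nᵢ−1), so the default ("normal") range is
μ̂ ± z₀.₉₇₅·√(σ̂²_within + τ̂²).  A "t" variant adds the pooled mean's
squared standard error under the root and uses a t quantile with k−1
degrees of freedom, giving a prediction-style interval that accounts for
estimation uncertainty of μ̂; it is wider and matters only at small k.
The normal variant is the default because it is the one whose limits are
internally consistent with the packaged pooled tables (mean, SD and limits
agree through μ̂ ± 1.96·SD at printed precision).

**Rounding.** Limits are rounded half away from zero to the printed
precision of each parameter (0 dp for volumes/times, 1 dp for ratios and
areas).  The packaged single-study rows all satisfy
round(mean ± 2·sd, precision) == printed limits under this rule, which is
what `cmrnorms tables --verify` re-checks.

**Degenerate inputs.** Studies with n < 2 are rejected from pooling (the
variance of their mean is undefined); zero-variance studies are handled by
flooring vᵢ at the smallest positive float so weights stay finite.

## Pediatric growth models

**LMS.** z = ((X/M)^L − 1)/(L·S); for |L| < 10⁻⁵ the continuous limit
ln(X/M)/S is used (the cutoff is chosen where the power form starts losing
precision to cancellation, not at the theoretical L = 0).  Centile
inversion is X = M(1 + L·S·z)^(1/L) with an explicit error when
1 + L·S·z ≤ 0 (infeasible for strongly skewed L at extreme z).

The packaged pediatric tables equate the lower/upper reference limits with
z = ∓2 *and* with the 3rd/97th centile.  Those two statements differ
(Φ(−2) = 2.28%, not 3%); the package follows the tables' convention by
default — z = ±2 for the 3rd/97th columns, exact normal quantiles for the
inner columns — because that choice reproduces the printed cells.  Pass
`extreme_z2=False` for exact quantiles.

**Interpolation** between grid rows is linear per component (the source
tables say only "interpolated"; linear is the simplest choice that is
exact at grid rows).  No extrapolation: growth models are invalid outside
the fitted covariate range, so out-of-grid queries raise.

**Printed-cell verification.** Recomputing the packaged LMS tables'
printed centile columns reproduces every verifiable cell within ±1 unit
(85.7% and 80.0% exactly for the LA-boys and RA-girls blocks; the misses
come from the source's rounding of L, M, S to three decimals).  Two blocks
of the transcribed atrial tables (LA girls, RA boys) are internally
inconsistent *as printed*: their 50th-centile column deviates from their
own printed M by up to 6 units, which is impossible under the table's own
formula (the 50th centile of an LMS distribution is M by definition).
These blocks are packaged with a `centiles_discordant` flag in the sidecar
and their centile cells are excluded from verification; their L/M/S grids
remain available for scoring.  The flag criterion — |round(M) − printed
c50| > 1 — is definitional and independent of any convention chosen here.

**Regression z-scores.** z = (measured − predicted)/SD_residuals with
predicted = a + b·√BSA (vessel diameters) or a + b·BSA (areas).  Two
published area regressions come without a residual SD; they are packaged
as prediction-only models that refuse to emit a z rather than guessing a
spread.

## Classification and routing

A measurement record routes to the most specific applicable entry.
Kind precedence: LMS model > regression model > printed centile table >
plain range — a continuous z/centile beats a band.  Within ranges,
stratum specificity is lexicographic: special population (athletes) >
ethnicity > age band > sex > training-volume group > acquisition tags
(field strength, sequence).  Equal-specificity ties raise an error naming
the candidates instead of picking one; relaxometry rows, which differ only
by field strength/vendor/sequence, therefore require the record to carry a
matching `technique` tag.

Age bands follow the printed closed headers ("20–29") implemented as
half-open [lo, hi) intervals so adjacent bands tile the axis.  Printed
limits are treated as **inclusive** (a value exactly on a limit is within
range); the sources do not state inclusivity, so this is a documented
package convention.  Rows published as median [IQR] carry a distribution
tag and are excluded from z computation.

## Derived-quantity formulas

All are pure arithmetic in the units stated in the docstrings (areas cm²,
lengths cm → volumes mL; distensibility scaled to 10⁻³ mmHg⁻¹; [Fe] in
mg/g dry weight).  Noteworthy choices:

* **Transit time (foot-to-foot).** The sources name the estimator but not
  its numerical details.  Baseline = median of pre-peak samples below 10%
  normalized amplitude; upslope = least-squares line through the earliest
  contiguous pre-peak run of samples with 20–80% amplitude; foot = their
  intersection.  A midpoint variant (time at 50% amplitude, linearly
  interpolated) is provided because some cohorts used it.  Flat curves
  (amplitude below 4× baseline noise) raise a detection error; negative
  Δt is returned with a warning by `transit_time` but refused by `pwv`.
* **Iron grading** boundaries follow the printed inequality symbols:
  ">20 normal" makes 20.0 ms itself overload; the bare range "10–20" is
  closed at 10, so 10.0 ms is overload, not severe.  The three classes
  partition (0, ∞) at both field strengths.
* **Diastolic function** from MDT and E/A alone cannot separate normal
  from pseudonormal (type 2) — both print "normal MDT, E/A 1–2" — so the
  classifier returns the *set* of consistent classes rather than forcing
  a guess.
* **Box counting** uses fixed-origin grids with dyadic box sizes from
  2 px to a quarter of the shorter image side (the source descriptions do
  not specify sizes or origin handling), and FD = −slope of log count vs
  log size.  Stack summaries: global FD = mean over slices; maximal
  apical FD = max over the apical half, discounting the middle slice of
  an odd stack.
* **Synthetic hematocrit** ships no default calibration: the blood-T1 →
  Hct regression is scanner- and sequence-specific, so coefficients must
  be supplied; out-of-(0,1) results are clipped with a warning.

## Synthetic data

The generators emulate the statistical structure each stage assumes, with
a single seeded `numpy` Generator per call and no global state.

* `gen_study_aggregates`: θᵢ ~ N(μ, τ²), individuals ~ N(θᵢ, σ²),
  reported mean/SD are sample statistics — exactly the random-effects
  model the pooling assumes.  Defaults used in calibration runs are
  μ = 100, σ = 15, τ = 0, K = 10 studies of n = 200, a scale typical of
  the larger single-center cohorts in the packaged tables.
* `gen_lms_population`: inverse-transform sampling so the output's LMS
  z-scores are exactly the drawn standard normals; infeasible draws
  (1 + L·S·z ≤ 0) are rejected and the rejection rate reported (≈0.3% for
  the most skewed packaged parameters, 0 for most).
* `gen_flow_pair`: half-sine upstroke (80 ms) with exponential decay over
  a 1000 ms cycle, distal copy delayed by Δx/PWV, optional multiplicative
  Gaussian noise.  These template constants are physiologically plausible
  and irrelevant to recovery accuracy, which depends on the sampling
  interval.
* `gen_fractal_image`: rasterized line, Koch curve, square boundary and
  filled square of known dimension for validating the box counter.

What the generators do **not** emulate: real studies' non-normal tails,
reporting/rounding of published aggregates, correlated multi-parameter
cohorts, physiological waveform variability (reflected waves, baseline
drift), or partial-volume effects in masks.  Passing tests therefore
demonstrate correctness of the estimators under their stated models, not
robustness to every artifact of real acquisitions.

## Numerical calibration checks

Simulation sizes were chosen to make Monte-Carlo error small relative to
the tolerances: 500 replicates for the 0.975-quantile calibration of the
pooled range (the acceptance script's `t8`; a seed-to-seed spread well
under 0.001), 200 replicates for estimator-recovery and τ²-truncation
properties, 10⁴ samples for distributional (KS) checks.  The Koch-curve
raster uses 5 iterations at 512 px, where segment length (~2 px) matches
pixel scale; finite line width biases box-counting FD upward by ~0.03,
within the 0.05 validation tolerance.

## Known limitations

* The packaged tables are a curated subset of the published compendia —
  enough to cover every table kind and the classification workflows; the
  store format (CSV + JSON sidecar per table, user-extensible via a
  directory flag) is designed for adding the remainder.
* The exact frequentist interval construction used by the published
  pooled tables (normal vs t quantile, inclusion of se(μ̂)) is not
  recoverable from rounded printed values; both variants are exposed.
* No unit conversion beyond the registry's declared units, and no DICOM
  or image segmentation — fractal analysis expects binary masks.
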