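# cmrnorms

Normative reference ranges ("normal values"), pediatric z-scores and derived
biomarkers for quantitative cardiovascular magnetic resonance (CMR).

Quantitative CMR reports chamber volumes, myocardial mass and function,
vessel dimensions and stiffness, and tissue relaxation times.  Interpreting
any of these requires a reference range — the interval expected to contain
the central 95% of a healthy population — and those ranges are published as
*aggregated* statistics: per-study sample sizes, means and standard
deviations, LMS growth-model parameters, regression coefficients against
body surface area, or centile-by-height tables.  `cmrnorms` is for imaging
scientists and clinical researchers who need to (a) build reference ranges
from such study-level aggregates, (b) evaluate pediatric z-scores and
centiles from published model parameters, (c) compute the standard derived
CMR quantities, and (d) classify individual measurements against an
auditable, versioned table store.

## What it computes

**Reference ranges from aggregates** (`cmrnorms.refrange`).  For a single
study, mean ± 2·SD.  For several studies reporting (nᵢ, x̄ᵢ, sdᵢ) for the
same parameter, a DerSimonian–Laird random-effects model: with
within-study variances vᵢ = sdᵢ²/nᵢ and fixed-effect weights wᵢ = 1/vᵢ,

    τ̂² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)),   Q = Σwᵢ(x̄ᵢ − x̄_w)²

and the pooled mean μ̂ = Σwᵢ\*x̄ᵢ / Σwᵢ\* with wᵢ\* = 1/(vᵢ + τ̂²).  The
95% reference range estimates the 2.5th/97.5th *population* quantiles,

    μ̂ ± z₀.₉₇₅ · √(σ̂²_within + τ̂²)

where σ̂²_within = Σ(nᵢ−1)sdᵢ² / Σ(nᵢ−1).  Printed limits are rounded half
away from zero to the parameter's measurement precision.

**Pediatric normalization** (`cmrnorms.growth`).  The LMS (Box–Cox) model:
z = ((X/M)^L − 1)/(L·S), with centiles X = M(1 + L·S·z)^(1/L); parameters
are interpolated linearly in age/height/BSA between grid rows.  Regression
z-scores z = (measured − predicted)/SD_residuals with predicted = a + b·√BSA
(or a + b·BSA).  Printed centile tables are bracketed and interpolated.

**Derived quantities** (`cmrnorms.formulas`).  DuBois/Mosteller BSA,
BSA indexing, area–length atrial volumes (monoplane 8A²/3πL, biplane
ellipsoid (8/3π)·A₁A₂/L, calibrated 0.848·A₄A₂/mean length), LV sphericity,
aortic distensibility (Amax−Amin)/(Amin·ΔP), pulse wave velocity Δx/Δt with
foot-to-foot transit-time estimation from velocity waveforms, ECV from
pre/post-contrast T1 and hematocrit, synthetic hematocrit from native blood
T1, R2* = 1000/T2*, cardiac iron [Fe] = 45·T2*^−1.22 with overload grading,
aortic-stenosis staging, diastolic-function classes, and box-counting
fractal dimension of binary trabeculation masks.

**Table store** (`cmrnorms.registry`).  Packaged CSV tables (one per
published table, with a JSON sidecar holding the title, population and
method) cover adult LV parameters, athlete LV/RV parameters, pediatric
atrial-volume LMS grids and centile tables, pediatric aortic/pulmonary
regression models, aortic distensibility/PWV LMS grids, pulmonary artery
dimensions, and pediatric T1/T2/ECV rows.  `Registry.classify` routes a
measurement to the most specific applicable entry (population > ethnicity >
age > sex) and returns a status, z-score, centile and provenance string;
equal-specificity ties raise an error naming both candidates.

## Worked example

```python
import cmrnorms as c

reg = c.load_default_registry()

# An adult man with LVEF 50%
r = reg.classify(c.MeasurementRecord(parameter_id="lvef", value=50,
                                     sex="male", age=50))
print(r.status, round(r.z, 2), r.provenance)
# below_range -2.29 lv_adult_bssfp_mass_conv:lvef/male

# A 6-year-old boy with indexed maximal LA volume 14.39 mL/m²
r = reg.classify(c.MeasurementRecord(parameter_id="la_max_vol_bsa",
                                     value=14.39, sex="male", age=6))
print(r.status, round(r.z, 2), round(r.centile, 1))
# below_range -2.0 2.3

# A single-study pediatric native-T1 range (mean 1017 ms, SD 48 ms)
rr = c.mean_sd_range(1017, 48)
print(rr.lower, rr.upper)
# 921.0 1113.0
```

The LVEF 50% is 2.29 SD below the pooled adult-male mean of 66 ± 7% and
falls under the 53–79% reference range, so it is flagged `below_range`.
The boy's LA volume sits exactly on the z = −2 lower limit (≈ the 3rd
centile of the LMS model interpolated at age 6).  The T1 range reproduces
the printed 921–1113 ms limits.

A CLI wraps the same functionality:

```sh
cmrnorms classify measurements.csv          # parameter_id,value,sex,age,...
cmrnorms pool studies.csv --decimals 0      # study_id,parameter_id,n,mean,sd
cmrnorms pwv proximal.csv distal.csv --delta-x 0.3
cmrnorms simulate flow --seed 5 --out-dir sim
cmrnorms tables --verify                    # re-check packaged-table invariants
```

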