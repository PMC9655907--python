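# Methods

## Scope and data model

The pipeline covers the quantitative chain of a strain-improvement study of
an oleaginous microalga: plasma-mutagenesis dose selection, growth and
productivity of the selected mutants, biochemical composition, and the
FAME-profile-based estimation of biodiesel fuel properties checked against
ASTM D6751 and EN 14214. The in-memory containers are small frozen
dataclasses (`FattyAcid`, `FameProfile`, `BiodieselProperties`, …) with
pandas DataFrames at the I/O boundaries.

## FAME profiles and class summaries

Profiles are compositional vectors of relative percentages keyed by parsed
species identity. Parsing accepts `C<carbons>:<double_bonds>` with an
optional `(ω<n>)` (or `(w<n>)`) suffix; chains shorter than C4 are rejected
and odd chain lengths warn, since algal FAME panels are even-chain C8–C26.
Isomers that differ only in ω annotation are distinct keys and simply add
in class totals — the packaged panel contains both annotated and
unannotated C18:1, and merging them would silently change MUFA.

Not-detected markers (`–`, `-`, empty, `ND`) are zeros, not missing values:
a species below the GC-MS detection limit contributes nothing to class
totals or ADU. Loaded columns must total within [95, 105]% (the packaged
columns sum to 99.0–100.1); `normalize()` rescales to exactly 100 but is
*not* applied by default, so class totals mirror the raw table. The
reported wild-strain PUFA of 35.9% only reproduces on raw percentages,
which fixed the default; `renormalize=True` is available everywhere.

ADU uses mass fractions on the 0–1 scale, so a pure C18:1 profile has
ADU = 1 and the panel spans 0.48–1.16. Db≥4 counts species with ≥4 double
bonds literally; the C18:3 total is a separate field because the standards
cap linolenate specifically.

## Fuel properties and standards

The six property regressions and the CFPP–LCSF line are applied at full
precision; rounding to 2 decimals happens only at serialization, and
compliance always compares unrounded values. LCSF defaults to the
five-term literature form (0.1, 0.5, 1.0, 1.5, 2.0 weights on C16:0–C24:0);
this is the only form that reproduces the published M8 LCSF of 11.23 from
its profile, and a four-term variant (no C22:0) is available by flag.

Standards are a versioned JSON resource mapping property → interval.
Printed `≥`/`≤` bounds are closed (equality passes); the ASTM cloud-point
`> 4` is the one open bound. Properties a standard does not limit are
reported `not-limited` and never affect the overall verdict.

Two quantities are deliberately *not* reconciled with their published
counterparts and are instead flagged on every report:

* the cloud point from the ADU regression is far from the published Cp row
  for every strain (e.g. 15.1 vs 0.32 at ADU 1.47), so reports carry a
  `cloud_point_regression_not_validated` flag;
* an ADU recomputed from a profile can differ substantially from a
  published ADU for the same strain (M8: 0.48 vs 0.87). The default policy
  uses the supplied ADU when one is given, records `adu_source`, and raises
  an `adu_source_mismatch` flag when the two differ by more than 0.05;
  `adu_policy="profile"` forces recomputation.

## Growth, screening, assays

µ is the log difference of dry weights over a user-chosen exponential
window (default days 2–16, matching the observed lag and stationary onset);
an automatic maximal-R² window scan over ln(DW) is provided as an
extension. OD-only series are converted through the least-squares
calibration before any rate computation; measured dry weights take
precedence over converted OD. Productivities are reported as positive
magnitudes |late − early|/Δt with the window recorded — the sign convention
of the defining difference would make growing cultures negative — and a
`signed=True` option preserves the raw sign.

Mortality is (1 − T/C) × 100 from treated/control colony counts, clamped to
[0, 100] with a warning when T > C. Dose selection takes the smallest
exposure reaching the mortality threshold (default 95%, where the positive
mutation rate is considered highest) that still leaves at least one
surviving colony — a fully lethal dose leaves nothing to screen. Mutant
ranking filters to strains beating the wild type on both growth rate and
lipid content, then orders lexicographically by lipid fold (growth-first
available); the lexicographic rule is a design choice where the underlying
practice is a qualitative "comprehensive analysis".

Pigments use the three-wavelength chlorophyll equations with the Chl b
coefficient taken as 19.07 on A644 — the only magnitude consistent with the
10.3 Chl a coefficient and with chlorophyll spectrophotometry — with an
override parameter. Negative pigment or analyte values (blank-subtraction
noise) are floored at zero with a warning, never an error. Standard curves
are ordinary least squares; inversion outside the calibrated concentration
range sets an `extrapolated` flag.

## Synthetic data

Generators give every stage inputs with recorded ground truth; each takes a
frozen config carrying its own seed and builds one `default_rng` per call,
so outputs are reproducible in isolation and in any order.

* **Growth** (defaults: dw₀ = 0.025 g/L, K = 0.65 g/L, µ = 0.20 day⁻¹,
  2-day lag, log-normal noise σ = 0.05, sampling every 2 days to day 20)
  uses a piecewise lag/exponential/plateau trajectory rather than a
  logistic. The choice is deliberate: a logistic's log-slope is
  µ(1 − x/K), which at these inoculum-to-capacity ratios biases any
  finite-window µ estimate ~4–7% low, conflating generator shape with
  estimator error. The piecewise form matches the emulated phenomenology
  (lag to day 2, exponential to ~day 16, then stationary) and makes µ
  exactly identifiable in the noiseless limit.
* **Mortality** (t50 = 33 s, steepness 0.5 s⁻¹, 319 control colonies over a
  10–60 s grid) draws binomial colony counts on a logistic survival curve.
  The defaults put ~97% expected mortality and ~9 expected survivors at
  40 s and full lethality beyond, so the designed optimal dose — computed
  from expectations alone by `designed_dose` — is 40 s, the regime the
  emulated screening describes (95.3% mortality, 15 colonies).
* **FAME profiles** are Dirichlet draws (precision 500, giving ≈0.5–2%
  per-species scatter) centered on one of the six packaged archetype
  columns; only detected species receive jitter, so not-detected zeros are
  preserved, and every draw sums to 100 exactly.
* **Screen records** draw log-normal growth/lipid folds around the wild
  strain (mean ln-fold 0.05; σ 0.30 growth, 0.15 lipid), which makes
  roughly a third of mutants beat the wild type on both axes — the
  realistic yield of a random-mutagenesis screen.
* **Assays** are linear signal = slope·conc + intercept plus Gaussian
  noise, clamped at zero signal (flagged) since absorbance cannot be
  negative.

What passing recovery tests shows is limited to these mechanisms: real
growth curves have correlated, heteroscedastic errors and density-dependent
transitions; real screens have correlated trait shifts; real GC-MS
compositions have detection-limit censoring beyond simple zeros. The tests
demonstrate estimator correctness under the stated noise models, not
field-data robustness.

## Numerical choices and problem sizes

Least squares is `scipy.stats.linregress` throughout; no other fitting is
involved. Dose-selection ties are broken toward the smaller exposure by
construction (first qualifying row after sorting). Degenerate inputs —
zero-total profiles, all-equal calibration abscissae, Δt ≤ 0, zero control
counts — raise typed errors naming the offending strain or quantity.
Report JSON is serialized with sorted keys and no timestamps, so identical
configs give byte-identical files.

The recovery studies use 100 seeded growth/calibration replicates and 200
seeded mortality tables — enough for stable medians and rate estimates
(binomial s.e. ≈ 1% at 200 draws) while the whole suite and the acceptance
script each run in seconds.

## Known limitations

Relative percentages only (no mg-per-gram absolute FAME quantification);
empirical linear property models only, with no group-contribution or
thermodynamic alternatives; no chromatogram processing; no
mutation-rate-vs-dose biology beyond the survival sigmoid; significance
testing (ANOVA/post-hoc letters) is out of scope and left to standard
statistics packages.
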