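# Methods

## The decision model

The package decides whether a scoliosis brace exerted adequate pressure
from a single post-removal image pair. The physical rationale is the
thermoelastic effect: under near-adiabatic conditions, surface stress
changes relate linearly to surface temperature changes, so sustained
brace pressure leaves a locally warmer region on the skin. The pipeline
never models the thermoelastic relation quantitatively (tissue density,
specific heat, stress/strain tensors are not parameters anywhere); it
only assumes the *consequence* — a pressure-proportional temperature
elevation ΔT in the pressure region — and tests for it statistically.

The statistic is deliberately relative, not absolute: ROI #2 is the
mirror image of the operator-selected ROI #1 across the backbone axis,
so each patient serves as their own control and inter-patient differences
in absolute skin temperature, emissivity handling and camera bias drop
out. Concretely, both ROIs are jointly min–max rescaled to [0, 1],
partitioned into `N × M` subregions whose means form two vectors of
length `L = N·M`, and compared with a pooled-variance two-sample
Student's t-test (`df = 2L − 2`, two-sided). The adequate call requires
`p < th` *and* `mean(v₁) > mean(v₂)`: directionality is enforced by the
mean-ordering condition rather than a one-sided test, so a significantly
*colder* pressure region is classified inadequate (with a warning).
The `p < th` comparison is strict; `p = th` is inadequate.

Assumptions worth stating explicitly:

* the partition means are treated as two independent samples (unpaired
  test). Partitions do correspond spatially across the mirrored ROIs, so
  a paired test would be defensible; the unpaired "two groups" reading is
  implemented.
* a χ² goodness-of-fit normality check (equal-probability binning,
  `k = max(4, ⌈√L⌉)` bins, `k − 3` degrees of freedom) is computed per
  vector but is advisory: it is logged, never a gate.
* the backbone axis is a single vertical column; oblique spines and
  misregistration between the RGB and thermal streams are out of scope
  (registration is pure anisotropic scaling).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_rows`, `n_cols` | 4, 4 | partition grid; `L = 16` gives the t-test a workable sample size for the 20–30-px thermal ROIs typical at 160×120 resolution |
| `threshold` | 0.05 | decision p-value threshold for one-off assessments |
| grid | 0.005–0.500, 1000 points | linearly spaced candidate thresholds for evaluation-time training, endpoints included (step ≈ 4.955·10⁻⁴) |
| `n_subsets`, `per_class` | 10, 10 | balanced-subset construction for imbalanced studies |
| `coverage_k` | 2 | expanded-uncertainty coverage factor (≈95% under normality) |

The partition counts are exposed because no canonical value exists; 4×4
is a compromise between per-block averaging (noise suppression) and
sample size for the test. Sensitivity can be explored via config.

## Grayscale normalization choice

Normalization is joint over the ROI pair, not per ROI. Per-ROI min–max
would force both vector means toward similar values and destroy exactly
the between-ROI contrast the decision tests; joint scaling is the only
monotone affine reduction under which "ROI #1 is warmer than ROI #2"
survives the conversion. A convenient corollary, asserted by property
tests: any temperature offset common to both ROIs (per-image camera
bias) cancels exactly. A degenerate pair with zero joint range maps to
all-0.5, keeping the statistics defined and yielding the correct
inadequate call.

## Evaluation machinery

Scores are `(p_value, direction_ok, label)` triples. Because adequate
cases dominate clinical datasets (26 vs 10 in the reference study
design), evaluation builds 10 balanced subsets: each contains *all*
label-0 instances plus 10 label-1 instances drawn without replacement,
subset *i* using seed `seed + i` (a fresh seed per subset, fully
reproducible). Per subset, leave-one-out cross-validation trains the
threshold on each fold by grid search; among equally optimal training
thresholds the *smallest* is chosen — deterministic and conservative
(fewest positives declared). Subset accuracy gets a type-A standard
uncertainty `u = s/√n = √(p̂(1−p̂)/(n−1))` (as a percentage); the subset
accuracies are averaged and their uncertainties combined by the
first-order propagation law for a mean of uncorrelated quantities,
`u_m = √(Σu_i²)/n`, then expanded with `U = k·u_m`. All quantities are
carried at full precision internally; only human-readable summaries
round to one decimal.

A known LOOCV edge case, frozen in the tests: with identical records and
balanced labels, the trained constant classifier always predicts the
training majority, which on a balanced set is the complement of the
held-out label — accuracy 0 when the constant prediction is positive,
50% when it is the constant-negative classifier.

## The phantom generator

The synthetic thermal frame is

```
T(x, y) = baseline + gradient·y + ΔT·exp(−d²/2σ²) + bias + ε,
```

quantized to `quantization_c` steps, with `d` the distance to the
hot-spot center; the RGB companion is a flat skin-toned image at the
photograph's resolution. Defaults emulate the acquisition conditions of
the reference study design: 33 °C baseline, 0.002 °C/px vertical trend,
σ = 6 thermal px, sensor noise sd 0.1 °C (the camera's 100 mK thermal
sensitivity), 0.1 °C quantization, per-image bias U(−3, +3) °C (the
camera's stated accuracy band), 160×120 thermal / 1440×1080 RGB frames,
and studies of 26 adequate + 10 inadequate records. ΔT for adequate
phantoms defaults to 1.0 °C — no quantitative pressure-to-ΔT magnitude
is established, so this is a free parameter that tests state explicitly.
ROI #1 is the ±2σ hot-spot box; ROI #2 its mirror about the frame
midline. Record *i* of a study uses seed `seed + i`; the per-image bias
draw is always consumed (even at range 0) so phantoms differing only in
bias range share identical noise fields.

What the phantom does *not* emulate — and hence what passing tests do
not show about real data: anatomical torso geometry and curvature,
irregular pressure-pad footprints (the decision statistic only consumes
partition means, so bump shape is secondary), time-resolved cooling
after brace removal, sweating and metabolic confounders, palette-encoded
thermal images, and RGB/thermal misregistration.

## Null calibration and the vertical trend

Under an exchangeable null (no hot spot, no trend) the two-sided t-test
p-value is uniform and the warm direction holds on half the draws, so
the adequate fraction at threshold `th` is `th/2`; the Monte-Carlo tests
verify this. The default vertical trend deserves a note: it is
deterministic structure *shared* by both mirrored ROIs (same row range),
so it inflates the pooled within-group variance without affecting the
between-ROI mean difference. The test is therefore *conservative* on
trend-bearing nulls — the false-adequate rate falls below `th/2` (at
default settings roughly 0.005 instead of 0.025 at `th = 0.05`). The
calibration checks consequently run with the trend disabled, since they
measure the statistic's calibration, not the trend's (benign,
specificity-increasing) effect; the power checks keep all defaults.

## Numerical and I/O choices

* Canonical thermal storage is a comma-separated text matrix of °C
  values written at full float precision (`%.17g`), so round trips are
  exact; a 16-bit count image + affine calibration sidecar is the second
  dialect. Skin emissivity (0.97) is metadata only.
* ROI mapping floors the origin and rounds the extent half-up
  (`floor(x + 0.5)`, platform-independent, no banker's rounding), with
  degenerate extents promoted to one thermal pixel. This endpoint
  rounding can displace a mapped rectangle by up to two thermal pixels
  relative to a nested partner at 1/9 scale, so nesting is preserved
  only up to that slack — the property tests assert exactly that bound.
* Degenerate statistics are total: identical constant vectors give
  `t = 0, p = 1`; zero pooled variance with unequal means gives `p = 0`
  with an infinite t statistic; a zero-variance normality input returns
  `p = 0` with a warning.

## Problem sizes in the shipped checks

The Monte-Carlo calibration check uses 2000 null phantoms at full camera
resolution (tolerance 3 Monte-Carlo standard errors); signal-recovery
checks use ten independent 36-record studies per condition. These sizes
keep every estimate's Monte-Carlo error well inside its asserted
tolerance while the whole suite stays fast.

## Known limitations

Single vertical backbone axis; unpaired rather than paired testing; no
nonparametric fallback when normality fails (the check is advisory by
design); no multiple-testing correction across a patient's two ROI
pairs; the phantom's Gaussian bump and flat RGB are idealizations. The
headline clinical accuracy of the reference study design depends on
patient data that is not distributed; only its aggregation arithmetic is
reproduced exactly, while the method's statistical behavior is validated
on phantoms.
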