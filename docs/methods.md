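# Methods

## Signal model and voxelwise relaxometry

Multi-echo gradient-echo signal in a voxel is modeled as mono-exponential
decay, S(TE) = S₀·exp(−TE/T2\*), sampled at six in-phase echo times
(4.92, 9.84, 19.68, 29.52, 36.90, 49.20 ms). Each voxel is fitted by
Levenberg–Marquardt nonlinear least squares with an analytic Jacobian,
initialised from the log-linear regression of ln S on TE. Log-linear
estimation alone is bias-prone at low SNR (log transformation inflates the
weight of late, noisy echoes), which is why the nonlinear refit is the
estimator of record. A voxel is marked invalid when fewer than three echoes
have positive signal (the log initialisation is undefined and such voxels
are noise-dominated), when the decay slope is zero or positive (T2\*
unbounded or negative), or when the optimiser fails. Relative measurement
uncertainty is the delta-method SD of T2\* — the square root of the T2\*
diagonal of RSS/(n−2)·(JᵀJ)⁻¹ — divided by the estimate.

Placental summaries pool all valid ROI voxels (no per-slice aggregation)
and use the **median**, because intra-placental T2\* distributions are
strongly non-Gaussian (spatial oxygenation gradients across lobules).
Fitted T2\* values **at or above 250 ms are excluded** (strict ≥) from both
the median and the uncertainty summary; such values indicate signal
contamination by amniotic fluid rather than placental tissue. The exclusion
is applied to fitted values, never to ground truth.

Placental volume sums per-slice masked voxel counts times the voxel volume
(default 1.75×1.75×3.5 mm³). Slices lost to motion are linearly
interpolated between the nearest present slices on either side, by slice
index distance; a missing slice at either end copies its single nearest
present neighbour.

## Normative gestational models

Five candidate forms describe a biomarker across gestational age t (weeks):
constant, linear, quadratic, cubic, and the logistic sigmoid
y(t) = p₁/(1+e^{p₂(t−p₃)}) + p₄. With p₂ < 0 the sigmoid falls from an
early plateau p₄ through an inflection at t = p₃ toward a late plateau
p₁+p₄. Within-pregnancy rates of change — centred finite differences
(mid-GA, ΔT2\*/ΔGA) over consecutive scans of one subject — are fitted with
the analytic derivative, dy/dt = −p₁p₂e^{p₂(t−p₃)}/(1+e^{p₂(t−p₃)})²,
a 3-parameter form.

Conventions:

* Polynomials are solved exactly by linear least squares; the logistic
  forms by nonlinear least squares with a data-driven start (p₄ = mean y
  before 20 weeks; p₁ = mean y after 34 weeks minus p₄; p₃ = 30; p₂ = −0.2)
  plus 20 multiplicative multistart jitters, because logistic fits are
  local-minimum-prone. The logistic forms carry an exact mirror symmetry
  (p₁,p₂,p₃,p₄) ↔ (−p₁,−p₂,p₃,p₁+p₄); fits are canonicalised to p₂ < 0.
* Parameter covariance is s²(JᵀJ)⁻¹ with s² = RSS/(n−k). The reported RMS
  residual is √(RSS/n) — the descriptive spread of the data about the
  curve — while s² (the unbiased residual variance) feeds the covariance
  and prediction SD. Both conventions are deliberate and live side by side.
* BIC = n·ln(RSS/n) + k·ln(n); the Gaussian constant common to all
  candidates cancels, so only differences matter. Selection takes the
  minimum; ties break toward fewer parameters; non-converged candidates are
  excluded with a warning.
* An exactly singular Jacobian flags the fit non-converged (covariance from
  the pseudo-inverse), never silently. Near-degenerate fits — e.g. the
  derivative model on nearly linear rate data, where the inflection runs
  away and uncertainties explode — are *reported with their huge standard
  errors* rather than failed: the degeneracy is real information.
* Confidence bands use the delta method with normal quantiles
  (CI = μ̂ ± 1.96·√(gᵀCg), g the parameter gradient of the curve);
  prediction bands add s² inside the root. Bands and curve-separation tests
  use a 10–40 week grid at 0.1-week steps. Two group curves are deemed
  significantly different wherever their 95% CIs fail to overlap; the
  result is reported as contiguous week intervals.

## Z-scores and percentiles

Scans are standardised against the UN reference fit:
z = (y − μ̂_UN(GA))/σ_pred(GA), with σ_pred the **prediction** SD. The
narrower curve-CI SD would shrink toward zero as the reference cohort
grows, inflating z-scores without bound; only σ_pred makes
reference-population z-scores unit-variance, and the package's tests
verify SD ≈ 1.00 on simulated reference cohorts. Percentiles are
100·Φ(z). Gestational ages outside [10, 40] weeks are refused rather than
extrapolated. Gestational windows are [10,20), [20,30), [30,40];
percentile histograms use twenty 5%-wide bins, left-closed right-open with
the last bin closed at 100. Group comparisons use the two-sample two-tailed
KS test (asymptotic p), Cohen's d with pooled SD, and — for binary
frequencies — the 2×2 chi-square test without continuity correction plus
relative risk with a Wald 95% CI on log RR. Both mean/SD and median
summaries of z are emitted. No multiple-testing correction is applied.

## ROC evaluation

Scan-level percentiles are scored with the orientation *low percentile ⇒
positive (adverse) call*: a scan is flagged when its percentile ≤ cutoff.
Thresholds sit at midpoints between consecutive distinct scores plus ±∞
sentinels, so every achievable operating point appears exactly once and
trapezoidal AUC equals the Mann–Whitney concordance probability with ties
counted half (property-tested against exhaustive enumeration). Youden's
J = sens + spec − 1 is maximised over the threshold set to give J_max and
C_opt (in percentile units). The primary contrast is PA vs UN; SA scans are
excluded from it. Each completed study contributes one point; a
max-severity subject-level aggregation (minimum percentile per subject per
window) is available as an option. No AUC confidence intervals and no
cross-validation: the evaluation is deliberately in-sample.

## Synthetic cohorts

The cohort generator emulates the reference study's statistical structure:
316 subjects by default; outcome groups UN/PA/SA at 62.6/22.2/15.2%; sites
at 179/316 and 137/316; 1/2/3 completed scans with probabilities
14/20/66%. A 3-scan subject visits all three gestational windows
(10–20/20–30/30–40 weeks), a 2-scan subject two distinct windows, a 1-scan
subject one window (uniform weights); gestational ages are uniform within
each window, which approximates the roughly flat per-week scan histograms
after the study widened its recruitment windows. Median T2\* follows the
group's sigmoid with i.i.d. Gaussian residuals at the published RMS (9.6 /
13.8 / 12.5 ms for UN/PA/SA); hemoglobin, SpO2, volume and T1 follow their
group-specific linear models. Hemoglobin units are treated as opaque
(the reference values are used verbatim).

What the generator does **not** emulate: subject-level random effects (all
scans are pooled, matching the reference analysis, so within-subject rate
pairs share a curve but have independent noise); site-specific T2\* offsets;
correlated residuals between T2\* and the ancillary variables; non-Gaussian
or heteroscedastic residuals. Passing tests therefore demonstrate that the
pipeline recovers its generative truth under the study's idealised
statistical assumptions — not that real placental data satisfy them.

Noise in the phantom generator is additive Gaussian on signal magnitude
rather than Rician: at the SNR regimes exercised here the distinction is
negligible. One integer seed expands to per-subject substreams
(`SeedSequence.spawn`), so enlarging a cohort never reshuffles earlier
subjects and identical configs reproduce byte-identical tables.

## Problem sizes and numerical choices

The recovery experiments use the study-scale sizes they model: n=500 scans
for the sigmoid recovery (residual SD 9.6 ms, GA ~ U(11, 38)); n=700 / 450
/ 430 for the hemoglobin, T1 and SpO2 linear recoveries; 300 two-to-three
scan subjects for the rate-model recovery; ~560 UN scans (250 subjects) for
the normative-scoring check; 5000+5000 Gaussian draws for the ROC check.
Distributional tests use 10⁴–10⁵ draws. Phantom grids in tests are tens of
voxels per side — large enough for ellipsoid-volume and median-recovery
checks at their stated tolerances while keeping voxelwise fitting cheap.

Degenerate inputs are errors, not silent results: empty ROI, all slices
missing, duplicate gestational ages in a rate pair, single-class ROC input,
zero pooled SD, out-of-range gestational age. A single-class gestational
window inside `windowed_roc` is skipped with a warning since the remaining
windows are still informative.

## Known limitations

* No mixed-effects modeling; repeated scans are pooled as in the reference
  analysis, so parameter uncertainties ignore within-subject correlation.
* The normative reference and the scored scans may come from the same
  cohort (in-sample scoring), matching the reference design.
* T1 mapping reconstruction, motion/distortion correction and ROI
  segmentation are out of scope; masks and scalar T1 are inputs.
* Percentile-based discrimination assumes Gaussian residuals around the
  reference curve; heavy-tailed real residuals would distort tail
  percentiles.
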