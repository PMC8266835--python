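# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Quantification models

### Neuromelanin: ESNV and its skewness

NM-sensitive MRI is semiquantitative, so each SN voxel is background
corrected: `ESNV_i = S_i,SN − stat(S_crus)`, where the crus cerebri
background summary `stat` defaults to the **median** (robust to the
small sphere masks; the mean is available by flag). A subject's SN
state is summarized by the skewness of their ESNV distribution:
depigmentation replaces high-NM voxels with low-signal ones, producing
a longer low tail and a more negative third standardized moment. Two
estimators are exposed — the biased moment estimator
`g1 = m3/m2^(3/2)` and the adjusted Fisher–Pearson
`G1 = g1·√(n(n−1))/(n−2)` (default; what most statistics software
reports). At the SN mask sizes used here (≈ 530–2100 voxels) the two
differ by well under 1 %.

Bilateral ROIs **pool** left + right voxels into one distribution
before background correction and skewness; pooling (rather than
averaging two side-wise skewnesses) treats the bilateral SN as one
population of voxels, which matches how a bilateral dependent variable
enters the ROI statistics.

The normality check on the per-subject skewness values is a one-sample
Kolmogorov–Smirnov distance against a normal with the sample's own
mean and SD. Because the parameters are estimated from the same sample
the p-value is conservative (the Lilliefors correction is not
applied); it is used descriptively, not for inference.

### R2* relaxometry

Gradient-echo magnitude decays as `S(TE) = S0·exp(−R2*·TE)`. The
single-contrast estimator is ordinary least squares of `ln S` on TE
(slope = −R2*; TE supplied in ms, R2* reported in s⁻¹), exact on
noiseless data. With multiple contrasts of a multiparameter-mapping
protocol (PDw/T1w/MTw), a joint fit shares one decay slope with a
per-contrast intercept — the ESTATICS pooling idea — which on
discordant inputs returns the precision-weighted compromise of the
per-contrast slopes (stacked normal equations). Signals at or below a
relative floor (10⁻⁶ of the series maximum) are clamped before the log
and the voxel flagged. The fit is unweighted in the log domain: no
Rician correction, accurate in the high-SNR regime the phantom
emulates and a documented limitation for low-SNR echoes.

As a quality-control, region-median R2* can be regressed on published
post-mortem regional iron concentrations; a reference table of the
classic adult values (mg Fe/100 g fresh weight, after Hallgren &
Sourander 1958) ships with the package.

### Patlak Ki mapping

For irreversibly trapped [¹⁸F]DOPA, the reference-tissue Patlak
linearization is

    y(t) = C_t(t)/C_ref(t) = Ki · x(t) + V,   x(t) = ∫₀ᵗ C_ref / C_ref(t)

with occipital cortex (no specific uptake) as reference. Frame values
are frame-averaged activities; the running integral of the reference
is the trapezoid rule over frame mid-times anchored at (0, 0). The
generator uses the identical convention, so noiseless recovery of Ki
and V is exact to machine precision (verified to ≤ 10⁻⁸ in the
acceptance suite). The fit is unweighted OLS on frames with mid-time
≥ t* (default 30 min; with the clinical framing 6×10, 8×30, 5×120,
15×300 s this retains exactly the 12 five-minute frames, mid-times
32.5–87.5 min); frame-duration weights are available by flag. Frames
with non-positive reference activity are dropped with a warning. No
decay correction is applied (assumed done in reconstruction).

## Voxelwise statistics

Every analysis is a per-voxel GLM with a shared design: per-group
intercepts, centered age, sex, and — for interaction analyses —
group-specific slopes of a grand-mean-centered covariate (lateral-SN
ESNV skewness or lateral-SN median R2*). Group effects are one-tailed
in the pathophysiologically expected direction (R2*: PD > HC; Ki:
HC > PD); slope-difference contrasts are two-tailed, since the
direction of cross-modal couplings is genuinely open.

Family-wise error over a search mask is controlled by **max-statistic
permutation** with Freedman–Lane nuisance handling: the reduced
(nuisance-only) model is fitted, its residuals are permuted across
subjects, the nuisance fit is added back, and the full-model t-map is
recomputed; the corrected peak p is `(1 + #{perm max ≥ observed peak})
/ (1 + B)`, never below `1/(1+B)`. This replaces parametric
random-field-theory inference — the one intentional methodological
substitution — because it is exact under exchangeability and needs no
smoothness estimate, which parametric FWE could not deliver honestly
on compact phantom grids. Small-volume correction restricts the max
statistic to each anatomical mask in a single shared permutation pass,
and optionally Bonferroni-scales the corrected p by the number of
masks tested (two, matching the paired-mask inference families).
Under the all-effects-zero phantom the rejection rate at α = 0.05 is
measured by the acceptance suite over 200 replicates and must lie in
[0.03, 0.07]. Ties in the max statistic are broken by the ≥
comparison. The Z-map is the probit of the t CDF, computed tail-wise
for numerical stability; peaks are reported in world mm via the
affine.

## ROI statistics

ESNV skewness (4 SN tiers × all subjects, long format) is analysed
with a linear mixed model — identity link, REML, subject random
intercept — with fixed effects of group, ROI, and their interaction.
The continuous response makes the identity-link LMM the natural
reading of a "generalized" linear mixed model here. F tests are Wald F
with containment-style denominator df: the between-subject group
effect uses n_subjects − 2 (so with 46 subjects the group contrast is
a t on 44 df); ROI and interaction terms use the within-subject
residual df. Group comparisons are least-square means with a Tukey
(studentized-range) adjusted contrast, which with two groups reduces
to the unadjusted t test but is applied regardless. On balanced data
the LS-mean difference equals the raw group-mean difference exactly
(tested).

Demographics use the Pearson chi-square without continuity correction
(reproducing 0.3485 on the 13:10 vs 11:12 sex table) and the
pooled-variance two-sample t (the printed age summaries 67.3 ± 9.9 vs
67.7 ± 9.7, n = 23 each, give t(44) = −0.138). Clinical correlations
(UPDRS III, duration, H&Y, LEDD) are exploratory Pearson r with
unadjusted p, pairwise deletion. The ROI-level triple interaction
fits OLS of putamen Ki on group × centered lateral-SN R2* ×
putamen-ROI with all lower-order terms; with 2 groups × 2 ROIs the
three-way term has 1 numerator df and its F is the squared t.

## The synthetic phantom

The generator produces, on a common 1 mm grid (default 48×56×48), a
probabilistic atlas (0–10 a.u.) whose eight anatomical ROIs are
quadratic-profile ellipsoids scaled so that thresholding at 4 a.u.
recovers the four SN tier volumes at their published sizes (164, 130,
137, 100 mm³ for left/right medial and left/right lateral) within the
±20 % discretization tolerance. Putamen quadrants keep the anatomical
ordering but are scaled to 1/8 volume so all ROIs fit disjointly on
the compact grid. Crus cerebri masks are two 14 mm³ spheres ("14-mm³"
is read as sphere *volume*; the alternative reading of 14 mm diameter
is noted as ambiguous and the volume is configurable); an occipital
slab serves as PET reference; mean GM/WM probability maps support the
explicit GM mask (GM > WM and GM > 0.20, strict inequalities).

Per subject the generator emulates:

* **NM volume** — SN voxels drawn iid from a moment-matched shifted
  (sign-reflected) gamma with the subject's target skewness
  (`k = 4/γ²`; closed-form skewness `2/√k` makes the family its own
  oracle), around the crus baseline. The family describes the
  *measured* voxel distribution — acquisition noise is part of what
  the skewness summarizes — so measurement noise is added to
  background and crus but not re-added on the SN draw; re-adding it
  would attenuate the stated target by `(σ_s²/(σ_s²+σ_n²))^{3/2}` and
  make the generator's own contract unrecoverable.
* **Multi-echo series** — mono-exponential decay at the subject's true
  R2* field: SN baseline (default 30 s⁻¹ over a 20 s⁻¹ background)
  plus a severity-proportional elevation (default max 6 s⁻¹) confined
  to the lateral SN tier of the *affected* hemisphere, so that the
  analysis-side flip gathers every subject's elevation on the left.
  Additive Gaussian noise (default SD 5 on S0 1000) — Gaussian rather
  than Rician, the high-SNR limit, a documented limitation.
* **Dynamic PET** — frames exactly Patlak-consistent at the frame-
  average level: `T_k = Ki·X_k + V·R_k` with the reference bi-
  exponential `C_ref(t) = A(e^{−at} − e^{−bt})` integrated analytically
  per frame and X the shared trapezoid integral. Putamen Ki defaults:
  0.012 min⁻¹ baseline, severity-proportional reductions of max
  0.006 (posterior) and 0.003 min⁻¹ (anterior); occipital voxels carry
  the reference itself (Ki = 0, V = 1). Multiplicative frame noise at
  5 % CV.

A latent severity `d_i ∈ [0,1]` (0 for controls, Uniform(0.25, 1) for
patients) drives all three modality effects jointly by default
("coupling"), producing the within-PD correlations the interaction
analyses test; coupling can be switched to independent severities, and
`EffectSpec.null()` zeroes every group effect for null calibration.
Between-subject baseline variability (SN R2* SD 1 s⁻¹, skewness-target
SD 0.08, putamen Ki SD 0.0008 min⁻¹) jitters each subject around the
population values: real control cohorts show this spread, and without
it the control group's covariate column is constant up to measurement
noise, making group-specific slopes unidentifiable. The ground-truth
table records each subject's realized (jittered) baselines, so
recovery is always judged against the truth actually generated.

Signals are painted on mid-sagittally *symmetrized* ROI regions
because the published ROI volumes are left/right-asymmetric: flipping
an asymmetrically painted region would otherwise expose background
voxels under the analysis masks, an artifact that continuous real
anatomy does not produce. A fixed fraction of patients (default 7/23)
carries right-predominant signs and has maps flipped. One master seed
spawns independent child streams for the roster and each subject, so
outputs are reproducible and subject data do not depend on cohort
ordering. Clinical scores (UPDRS III, H&Y, duration, LEDD) are
noisy monotone functions of severity, giving the correlation module
realistic inputs.

What the phantom does **not** emulate: realistic anatomy and partial
voluming, motion and scanner artifacts, Rician magnitude statistics,
arterial input functions, radioactive decay, spatial normalization
(all subjects share the grid by construction). Passing tests therefore
demonstrate correctness of the estimators and validity/power of the
statistics under the stated generative model, not robustness to
real-data artifacts.

## Calibration of the acceptance-scale studies

Problem sizes were chosen once so the full suite runs comfortably on a
single CPU: parameter recovery uses 12 subjects per group on the
default grid; replicate studies (interaction localization, null
calibration) use a trimmed 44×52×36 grid that holds the same ROI
layout. Recovery tolerances come from the estimators' sampling theory
at the default noise: log-linear R2* per-voxel SE ≈ 0.5 s⁻¹ averaged
over ≈ 140 ROI voxels (tolerance ±0.5 s⁻¹ on the group delta), Patlak
per-voxel Ki SE ≈ 0.002 min⁻¹ over ≈ 500 voxels (±0.001 min⁻¹), and
per-subject skewness sampling SD √(6/n) ≈ 0.1 at ≈ 540 SN voxels
(±0.15 on the group gap).

Interaction localization follows the pipeline's own processing: Ki
maps are smoothed (4 mm FWHM, brain-masked) before the voxelwise fit.
Unsmoothed maps leave iid Patlak noise driving the putamen peak and
localization is unstable; smoothing pools that noise, the shared
subject-level Ki jitter cancels in the posterior-vs-anterior
comparison, and the posterior-putamen localization rate at the default
effect sizes is 0.87–0.93 (one-off Monte-Carlo calibration over two
independent seed batches), against which the ≥ 80 % acceptance check
is run on fixed seeds.

## Numerical and degenerate-input choices

* Atlas thresholding is inclusive (≥); empty masks warn, not fail.
* Smoothing uses nearest-edge replication so constants are conserved
  on small grids; mask-weighted smoothing zero-fills outside the mask
  (NaN-safe) and leaves outside voxels untouched.
* `fit_glm` refuses non-finite values inside the analysis mask — an
  all-NaN statistic map would otherwise yield a fabricated argmax
  "peak".
* Design matrices are checked for full column rank with the collinear
  columns named; a constant covariate centers to zero and is rejected.
* Zero-variance samples: skewness raises ("degenerate sample"),
  pooled t raises, iron calibration with constant response returns
  R² = 0.
* Permutation p-values use the add-one estimator and never claim less
  than 1/(1+B); n_perm < 100 is rejected.
* `t_to_z` evaluates the upper tail via the survival function and the
  lower via the CDF, keeping the probit finite and monotone at |t|
  values where the naive CDF saturates.

## Known limitations

* Unweighted log-domain R2* fitting (no Rician weighting) biases
  estimates at low SNR; the phantom operates in the high-SNR regime.
* The KS normality p is conservative with estimated parameters.
* Mixed-model denominator df are containment-style, not
  Kenward–Roger; for the balanced 2-group × 4-ROI design they agree
  with the subject-level t test exactly (tested).
* Mask-weighted smoothing is a stand-in for tissue-weighted smoothing;
  it preserves within-mask means but ignores tissue-probability
  weighting.
* ROI-mean recovery from smoothed maps is attenuated (signal bleeds
  across the small SN masks); quantitative recovery therefore uses
  unsmoothed maps, smoothing being reserved for voxelwise detection.
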