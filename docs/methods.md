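# Methods

## The analysis pipeline

The pipeline measures how individual differences in pain ratings and in
evoked BOLD features determine the error of between-individual pain
decoding. Its stages:

1. **Cohort**: per individual, a ratings vector over trials and a
   trial-by-voxel feature matrix on a common grid (simulated here; any data
   in the same layout works through the I/O layer).
2. **Decoding models**: one univariate-response PLSR per individual, fitted
   by SIMPLS with automatic component selection.
3. **Transfer prediction**: every model applied to every individual's
   trials; MAE and MPB per ordered (training, test) pair; within- vs
   between-individual comparison by a two-sample t-test with kernel density
   summaries.
4. **Individual-difference metrics**: DIST_PAIN, DIFF_PAIN, and voxel-wise
   DIST_BOLD, DIFF_BOLD per pair.
5. **Correlation maps**: Pearson correlations of unsigned metrics with MAE
   and signed metrics with MPB across between-individual pairs, scalar and
   voxel-wise with FWE correction; a group predictive map from a one-sample
   t-test of coefficients across individuals.

## SIMPLS and component selection

SIMPLS (de Jong 1993) extracts orthonormal score vectors that maximize
covariance with the centered response, deflating the cross-product vector
through an orthonormal loading basis. For a univariate response it coincides
with NIPALS PLS1 (the test suite cross-checks against an independent NIPALS
implementation), and with as many components as the rank of the centered
feature matrix it equals the ordinary-least-squares solution.

Both blocks are centered and an intercept is returned, so the mean fitted
value on training trials equals the mean training rating. Two consequences
are load-bearing: resubstitution (within-individual) MPB is exactly zero,
and transfer bias reflects genuine distribution shift rather than scale
breakage. The component count is the smallest k whose cumulative training
R² (which decomposes exactly as Σqₖ²/SS_y over orthonormal scores) reaches
`r2_threshold` (default 0.95), capped at `max_components` (default 10); if
the threshold is unreachable the cap is used and a warning issued. Both
knobs are exposed because no principled universal value exists; 0.95/10 are
conventional.

Below full rank, PLSR coefficients are *not* equivariant under per-column
rescaling of the features (component directions depend on column scale);
equivariance holds exactly at full rank, where it is tested.

## Error and difference metrics

MAE and MPB are plain means of |predicted − actual| and (predicted −
actual); |MPB| ≤ MAE by the triangle inequality. Predictions are not
clipped to the 0–10 scale: clipping would bias MPB, which must stay a
faithful signed average. Within-individual prediction defaults to
resubstitution (the literal train-and-apply-on-the-same-trials reading); a
k-fold mode gives an honest cross-validated diagonal when wanted.

The Bhattacharyya distance between two trial samples is computed by the
Gaussian closed form on sample means and unbiased variances,

  DB = (m₁−m₂)²/(4(v₁+v₂)) + ½ ln[(v₁+v₂)/(2√(v₁v₂))],

with a variance floor of 1e−9 against degenerate samples. A shared-bin
histogram estimator (DB = −ln Σ√(p q)) ships behind
`estimator="histogram"` for sensitivity analysis; the Gaussian form is the
default because it is smooth, standard, and well behaved at 40 trials per
individual, where histogram estimates are noisy.

## Inference and multiple comparisons

Group predictive maps use a per-voxel one-sample t-test across individuals
with Bonferroni FWE correction over in-mask voxels — exact or conservative
at this scale. Zero-variance voxels take p = 0 (constant nonzero) or p = 1
(all zero) by sign convention and are excluded from significance.

Voxel-wise correlation maps default to parametric Pearson p-values with
Bonferroni correction, treating the n(n−1) ordered pairs as independent.
They are not: each individual appears in 2(n−1) pairs, and both the error
and the difference metrics carry strong per-individual main effects, so the
parametric null is anti-conservative by construction (the effective sample
size is closer to n than to n(n−1)). The default keeps this convention
because it is the common practice the pipeline models; for calibrated
inference, `inference="permutation"` permutes individual labels (relabeling
the error matrix, which preserves the dependence structure) and controls
FWE through the permutation distribution of the maximum |r| over voxels.
The calibration test in the acceptance suite uses the permutation mode,
since calibration is precisely what that mode exists for; the group t-map,
whose units (individuals) are independent, is calibrated under its default
parametric Bonferroni inference.

## The synthetic cohort generator

The generator emulates a laser-evoked pain experiment: 30 individuals, 4
stimulus energies × 10 trials in random order, ratings on a 0–10 visual
analog scale, and evoked-amplitude features on a 12×12×12 voxel grid with
four planted 27-voxel regions (two positive, one negative, one
sign-heterogeneous) over null background.

Ratings: R = clip(α_j + β_j·d + adaptation_slope·i + ε, 0, 10), with the
energy level as an equally spaced latent drive d (the simplest monotone
choice). Defaults are anchored to the behavioral statistics of the emulated
design: α_j ~ N(1.0, 1.3²) and β_j ~ N(1.6, 0.3²) put individual mean
ratings around 5 with an across-individual spread of roughly 2.6–7.6 and a
per-individual rating range near 8 once trial noise (SD 1.0) is added.
Clipping is applied after noise, matching the bounded scale. The optional
`adaptation_slope` drifts ratings across trials (habituation); it affects
ratings only, and no analysis stage consumes it.

Features: B = w_jv·(R − R̄_j + μ₀) + δ_jv + η, where μ₀ is the cohort-design
anchor level. Weights multiply the *within-individual* rating fluctuation
around a common level, so between-individual feature-mean differences are
carried entirely by the amplitude offsets δ — making the two
individual-difference channels (label shift and feature shift) independent
by construction, which is exactly the decomposition whose separate effects
the analysis measures. Coupling weights to the raw rating instead would
entangle the channels: the feature-mean difference would inherit the rating
difference, whose bias coupling has the opposite sign, and the two would
partially cancel.

Planted weights are ±0.03 signal-change units per rating point, putting
per-voxel signal SD slightly above the trial noise SD (0.05) — a detectable
but individually weak effect, as intended for a multivoxel decoding setting.
Amplitude offsets δ are drawn per individual per region (SD 0.1, shared
across a region's voxels, i.i.d. per voxel in the background), emulating
regional gain differences of vascular or anatomical origin; a within-region
shared offset is what makes the feature channel visible in prediction bias,
since a model's regional coefficient mass multiplies it coherently. The
sign-heterogeneous region draws a ±1 sign per individual with probability
½, realizing a modulator with real per-individual weights but zero group
mean. Trial timing (inter-stimulus intervals, rating delays) is not
simulated; trials are exchangeable units, which is all the trial-level
analysis consumes.

`generate_trial_timecourses` expands features into raw scan series
baseline·(1 + feature·h(k)) with a smooth evoked profile h that is 0 at the
onset scan and peaks at the 4th post-onset scan, so the feature module's
baseline normalization (subtract then divide the onset value) followed by
extraction of the 4th post-onset scan recovers the feature matrix exactly.
Scan indexing: the onset scan is index 0; "4th scan after onset" is index
4. The feature is the value at that scan, not a windowed maximum — a max
operator would be noise-biased upward.

What the generator does **not** emulate: hemodynamic convolution, head
motion, physiological noise, spatial autocorrelation beyond the planted
regions, or any coupling between adaptation and features. Passing tests
therefore demonstrate correctness of the analysis machinery and the
qualitative mechanisms, not performance on real scanner data.

## Problem sizes and determinism

The Monte-Carlo suites run the full default cohort (30 individuals, 1728
voxels) with 100 replicates for sign recovery, 50 for the
sign-heterogeneity dissociation, and 200 null replicates (planted weights
zero) for FWE calibration with 199 permutations per map; the whole suite
completes in about a minute on one CPU thanks to vectorized pairwise
metrics and BLAS-batched permutations. All randomness flows from one seed
through named sub-streams (stimulus order, individual parameters,
sign assignments, offsets, rating noise, feature noise), so any
individual's data — and any full run — is exactly reproducible.

## Known limitations

* Parametric voxel-wise correlation p-values are anti-conservative (see
  above); treat default maps as descriptive, and use the permutation mode
  for inference.
* The Gaussian Bhattacharyya estimator mis-measures strongly non-Gaussian
  trial distributions (e.g., ratings piled at the scale bounds); the
  histogram mode exists for such checks.
* With fewer than 3 individuals the group map, the within/between
  comparison, and the correlation stages are skipped (reported as absent),
  since the statistics are undefined.
* Real-data magnitudes of the correlation coefficients depend on
  heterogeneity levels that the generator only emulates; only signs,
  orderings, and structural identities are asserted by the test suite.
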