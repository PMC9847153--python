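# Methods

This note documents the models and procedures `ppdscore` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## The grayscale quantile-spread score

PPD symptoms (vascular streaking, parenchyma discoloration) darken parts
of a cut slice. After RGB → grayscale conversion with the BT.601 luma
weights (0.299, 0.587, 0.114 — the convention of MATLAB's `rgb2gray`, kept
for comparability with earlier image-based PPD work), the score of a slice
is the relative spread of intensities inside the region of interest:

    score = (Q97.5 − Q2.5) / Q97.5

* Quantiles are computed on the **raw ROI pixels** with type-7 linear
  interpolation (`numpy` default). A normalized 256-bin histogram is
  available as a report artifact (`imaging.roi_histogram`), but it is
  never the quantile estimator; any histogram-based estimate can differ
  from the score's quantiles by at most one bin width.
* Intensities are normalized to [0, 1]; integer images are divided by
  their code-value maximum, which together with the score's built-in
  scale invariance makes the score bit-depth independent.
* The 2.5/97.5 pair makes the spread robust to a few specular or shadow
  pixels while still responding once lesions exceed ~2.5% of the ROI.
  Consequently the score responds weakly below that lesion fraction —
  a floor set by the sensor noise spread (≈ 3.92 σ / μ for Gaussian
  texture noise), about 0.10 at the synthetic defaults.
* Degenerate inputs raise instead of returning 0: an essentially black
  ROI (Q97.5 ≤ 1e−6) is a photography failure, not absence of
  deterioration, and an ROI under 100 px is not scoreable.

A root's score is the arithmetic mean of its available proximal, central
and distal slice scores (1–3 slices, distinct positions).

### Region of interest

The reference workflow selected the ROI by hand, which is not
reproducible. Both modes are supported:

* **manual masks** — single-channel PNG (nonzero = ROI) or polygon CSV
  (`x,y` vertices, 0-based pixel coordinates), used unchanged;
* **automatic detection** — threshold (Otsu by default, or fixed), take
  the side of the threshold that is in the minority on the image border
  as foreground (so light-on-dark and dark-on-light setups both work),
  discard components below `min_component_px` (default 256), keep the
  largest connected component, fill interior holes (dark lesions fall on
  the background side of the threshold and must stay in the ROI), and
  erode by `peel_erosion_px` (default 10 px) to strip the darker peel
  ring. Detection is fully deterministic.

## Cohort aggregation and classification

* Contaminated roots are excluded before any averaging: grayscale cannot
  distinguish microbial discoloration from PPD. Contamination percentages
  are reported per cultivar × timepoint (rounded to integers). A fully
  contaminated cell yields a missing mean — never an imputed or zero one —
  and a warning.
* Per timepoint: arithmetic mean and sample SD (n − 1). Assessments at 0
  and 1 dph are pooled into one baseline timepoint.
* The **average PPD score** is the mean of the four time-point means at
  {0-or-1, 2, 4, 7} dph. Report tables round half-up to 2 decimals (plain
  banker's rounding would mis-report ties such as 0.285); full precision
  is kept internally and thresholds are compared unrounded.
* **Clustering**: Lloyd's algorithm with k-means++ initialization,
  `restarts` (default 100) independent seeded starts, at most 300
  iterations, empty clusters re-seeded from the point farthest from its
  centroid; the lowest-WCSS fit wins, and cluster ids are renumbered by
  ascending centroid mean so results are reproducible bit-for-bit. The
  implementation is in-package because the contracts (per-restart WCSS
  bookkeeping, deterministic seeding, the empty-cluster rule) are part of
  the specification; it is cross-checked against scikit-learn's KMeans
  objective in the test suite. The feature vector defaults to the
  (2, 4, 7) dph means — the time window in which the published clusters
  were formed; (0, 2, 4, 7) and standardized features are options.
  Default k = 7 matches the published cohort partition; with unknown
  third-party initialization, memberships are comparable only up to label
  permutation.
* **Status rule**: per cluster, `centroid_average` = mean over member
  cultivars of their average PPD score, and `centroid_peak` = max over
  2/4/7 dph of the member-mean trajectory. A cluster is *early* if
  `centroid_average ≥ 0.29`, else *delayed* if `centroid_peak < 0.33`,
  else *intermediate*. The 0.29 boundary is the published early/delayed
  cut; 0.33 separates the published delayed clusters (peak ≈ 0.27) from
  the intermediate ones (peak ≈ 0.36) and is exposed as a parameter. All
  members inherit their cluster's status. Applied to the bundled
  28-cultivar benchmark memberships, the rule reproduces the published
  status of every cultivar (verified by `tests/test_acceptance.py` and
  `scripts/acceptance.py`).

## Statistics

* **Pearson tests** use t = r·√((n−2)/(1−r²)) with n − 2 df, two-sided;
  validated against `scipy.stats.pearsonr`.
* **Method-equality drop-term F-test**: the dispersion model
  `sdPPD ~ mt * cv + tp` (response: per method × cultivar × timepoint SD
  of PPD scores) is fit by least squares with treatment-coded factors;
  each droppable marginal term (`tp`, `mt:cv`) is refit without and the
  drop1-style table reports Df, Sum_of_Sq, RSS, AIC = n·ln(RSS/n) + 2·edf
  (the `extractAIC` convention, which reproduces the published table's
  negative AIC magnitudes), F = (SS/Df)/(RSS_full/df_resid) and Pr(>F).
  Main effects contained in the retained interaction are not droppable
  (marginality), and incomplete factorials raise a rank-deficiency error.
  The design matrices are built in-package (fast enough for the
  1,000-replicate null calibration); statsmodels OLS is the independent
  reference in the tests. The raw dispersion data behind the published
  table are unpublished, so the table is validated by convention and
  simulation, not by reproducing its numbers.
* **One-way ANOVA** is the classical between/within decomposition; the
  LSD critical difference is t(1−α/2, N−k)·√(MSE·(1/ni+1/nj)) and the
  Tukey–Kramer HSD uses the studentized range quantile
  q(1−α, k, N−k)·√(MSE/2·(1/ni+1/nj)) via `scipy.stats.studentized_range`.
* **PCA**: active variables are centered and scaled to unit (sample) SD
  — chosen because the trait units are heterogeneous — and the
  correlation matrix is eigendecomposed. Individual coordinates have
  variance equal to the eigenvalue per dimension (n − 1 denominator
  throughout); eigenvector signs are fixed by making each axis's
  largest-magnitude loading positive. Supplementary variables take no
  part in the fit and are shown as their Pearson correlation with the
  coordinates per dimension (correlation-circle convention).
* Shapiro–Wilk screening and the two-sample t-test are standard published
  procedures delegated to scipy.
* DMC = 100 · dry/fresh mass (%); `dry > fresh` is rejected as a weighing
  fault.

## Synthetic data

* **Slice images**: a light parenchyma disc (mean 0.75, Gaussian texture
  noise SD 0.02) with a darker peel annulus (0.35, width 8 px) on a dark
  background (0.06), plus dark radial streaks and blobs (intensity drop
  0.45). The lesion count is Poisson(rate · deterioration), rate 40,
  drawn by thinning a seed-fixed lesion pool, so at a fixed seed the
  lesion set is *nested* in the deterioration level: raising the level
  only adds lesions, making score monotonicity exact rather than merely
  probable. Lesion shapes are a visual stand-in for vascular streaking;
  only their monotone effect on the intensity spread matters to the
  tests. Not emulated: illumination gradients, color casts, microbial
  discoloration, camera optics — so passing tests show the scoring
  machinery is correct, not that photography artifacts are handled.
* **Cohorts**: four archetype trajectories (flat-low delayed; mid-course
  peak that falls back; late jump; fast rise to ~0.5) bracket the
  published cohort's shapes (baselines 0.11–0.20, early plateaus
  0.45–0.55). Per cultivar a Gaussian random shift (SD 0.015) is added;
  per root and timepoint, Gaussian noise (default SD 0.05, inside the
  published per-cell SD band 0.01–0.21) truncated to [0, 1] by clipping
  (bias negligible at these noise levels), and a contamination flag
  (default probability 0.10). Replicates per cultivar × timepoint are
  drawn uniformly from 4–9.
* **Traits**: DMC ~ N(35, 4²) %, and the 4 dph score is built from the
  standardized DMC latent so their population correlation equals
  `target_r` exactly; HCN is negatively correlated with root diameter
  (default −0.5), length independent. The empirical mean r at n = 28 sits
  slightly below the target (the standard small-sample bias of r,
  ≈ r(1−r²)/2n ≈ 0.007 at r = 0.66), well inside the ±0.02 validation
  band.

## Validation experiments and problem sizes

`ppdscore.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) recomputes everything at run time:

* benchmark average-score column and status labels (28 cultivars, exact);
* score-formula identities (uniform, bimodal, scale invariance, sort
  oracle);
* clustering recovery: 100 seeds × 12 cultivars (3 archetypes × 4), noise
  SD 0.04 so the minimum archetype separation on the (2, 4, 7) dph
  features (0.217) is at least 5× the noise SD; k = 3, 100 restarts;
* drop-term null calibration: 1,000 replicates of the 2 × 9 × 2 factorial
  with Gaussian noise and no timepoint effect, rejection rate at α = 0.05
  expected in [0.03, 0.07];
* trait-correlation recovery: 2,000 replicates at n = 28, target r 0.66;
* byte-identity of repeated seeded writes.

These sizes were chosen to estimate each rate to about a percentage point
while keeping the whole validation run around ten seconds on one CPU.

## Known limitations

* The score saturates for lesion fractions below ~2.5% (quantile floor)
  and cannot separate microbial discoloration from PPD — contaminated
  roots must be flagged upstream.
* Automatic ROI detection assumes one slice per image with a roughly
  convex outline; overlapping slices or heavy vignetting need manual
  masks.
* Cluster *numbering* from third-party tools is not reproducible;
  comparisons are made up to label permutation, and the published
  memberships are consumed as data where exact correspondence matters.
* The published drop-term table and trait-correlation table rest on
  unpublished raw data; they are validated in schema, convention and by
  simulation only.
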