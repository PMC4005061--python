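# Methods

## The analysis in one paragraph

`alffpipe` implements a resting-state fMRI group analysis built around the
amplitude of low-frequency fluctuations (ALFF). Per subject, each voxel's
BOLD series is linearly detrended and taken to the frequency domain with a
plain DFT (no taper, no zero-padding, transform length = number of
volumes); the single-sided amplitude spectrum `a_k = (2/nt)|X_k|` is
averaged over the DFT bins falling in a low-frequency band (default
0.01–0.08 Hz, both edges inclusive) to give the voxel's ALFF. Each ALFF map
is divided by its global mean over the group intersection brain mask
(mALFF), removing per-subject scale. The standardized maps are spatially
smoothed, compared between two groups with a voxelwise ordinary
least-squares model that adjusts for a gray-matter covariate, and the
resulting t-map is thresholded per voxel (p < 0.05, two-tailed) and
corrected for multiple comparisons by a Monte-Carlo cluster-extent
threshold estimated from smoothed Gaussian null fields within the same mask
(the AlphaSim procedure).

## Statistics

**ALFF.** With `X_k` the DFT of the detrended series, `a_k = (2/nt)|X_k|`
and ALFF = mean of `a_k` over the in-band bins `k` with
`low ≤ k/(nt·TR) ≤ high`, `k ≥ 1`. The `2/nt` scaling makes a
unit-amplitude sinusoid on an exact bin contribute exactly 1 at that bin;
any other fixed positive scaling would cancel in the standardization
(ALFF is homogeneous of degree one in the signal, so mALFF is
scale-invariant — property-tested).

**Group model.** Per voxel, `y = Xb + e` with columns
`[1, group(+1/−1), gm]`, the gray-matter covariate mean-centered, and
`t = c'b / sqrt(s² c'(X'X)⁻¹c)` on `n − p` degrees of freedom, two-tailed
Student-t p-values. Without a covariate this is algebraically the classical
pooled-variance two-sample t (tested to 1e-8 against the textbook formula).
The covariate can be voxelwise (each subject's gray-matter map re-fills the
column at every voxel — an ANCOVA on images, the default) or a single
number per subject (e.g. mean gray matter in the mask). Voxels where the
covariate column is constant make the local design rank-deficient; they get
t = 0 / p = 1, are counted and logged, and never abort the map.

**Cluster correction.** Null fields are i.i.d. standard Gaussian noise on
the mask's bounding grid, smoothed at the declared FWHM
(`sigma = FWHM/sqrt(8 ln 2)` per axis, in voxel units), restricted to the
mask, and rescaled to zero mean / unit variance over the masked voxels —
without that rescale, smoothing shrinks the variance and the per-voxel
threshold would be silently conservative. Each field is thresholded at the
z-quantile of the voxel p (two tails clustered separately), connected
components are labeled (26-connectivity by default), and the largest
cluster size is recorded. The extent threshold at corrected level alpha is
the smallest integer `s` with `P_null(max cluster ≥ s) ≤ alpha`
(non-strict inequality: at alpha = 1 the threshold is a single voxel).
The realized family-wise error rate of the derived threshold is verified
on fresh null fields (held inside the binomial 95% interval around the
nominal level at n = 400).

## Design choices that were genuinely open

* **Spatial smoothing of the group maps.** Cluster-extent correction is
  only calibrated when the analyzed maps actually carry the smoothness the
  null simulation assumes. The pipeline therefore smooths the mALFF maps
  before the GLM, with the smoothing FWHM defaulting to the
  cluster-correction FWHM (8 mm); this mirrors how AlphaSim is used in
  practice (you declare to it the kernel your data were smoothed with). It
  is configurable off (`smooth_fwhm_mm = 0`), in which case the correction
  FWHM should be set to the maps' true smoothness.
* **Periodic boundaries in the null simulation.** Smoothing the null noise
  with wrap-around boundary conditions keeps the smoothed field exactly
  stationary, so a single global variance rescale is correct at every
  voxel, including near the grid boundary. The empirical per-voxel survival
  fraction then equals the nominal voxel p for any kernel width
  (property-tested at FWHM 0 and 8 mm).
* **Both band edges inclusive** in bin selection, with a 1e-12 absolute
  slack so edges that land exactly on a bin frequency are kept regardless
  of floating-point representation.
* **Two-tailed everything by default** (voxel threshold and cluster
  correction), since group differences in either direction are of interest;
  opposite-sign clusters are labeled separately even when adjacent.
* **Group coding +1/−1 with a separate intercept.** The t-statistic for
  the group contrast is invariant to this choice; the coding only fixes the
  sign convention (positive t = first/positive-coded group larger).
* **No resampling, ever.** All images in one analysis must share the voxel
  grid (shape + affine within 1e-4 mm); a mismatch raises, it is never
  interpolated away. Spatial normalization is upstream of this package.
* **TR precedence**: an explicit configuration value beats the NIfTI header,
  because headers are frequently wrong in archived data.
* **Anatomical labels are opt-in** (`annotate_regions`): the user supplies
  an integer label volume on the analysis grid plus a label→region lookup
  TSV; no atlas is bundled, since atlas choice and version are
  study-specific. Peaks outside the atlas, or with unlisted labels, are
  reported as "n/a".

## The synthetic cohort generator

The generator exists so the whole chain can be validated against known
ground truth. Per voxel, a subject's series is

* `n_lfo = 5` cosines with frequencies uniform in 0.01–0.08 Hz, uniform
  phases, unit base amplitude — the "neural" low-frequency oscillations;
* stationary AR(1) noise (`sigma_white = 1.0`, lag-1 `rho = 0.3`) —
  broadband thermal/physiological noise, inside and outside the band;
* 1/f-shaped noise (white noise whose DFT amplitudes are scaled by
  `f^(−1/2)`, `scale = 0.25`) — residual slow drift after detrending.

The 1/f scale was fixed so the drift's in-band amplitude is comparable to,
not dominant over, the oscillatory signal: detrended, preprocessed BOLD in
gray matter is oscillation-dominated in this band, and at scale 1.0 the
drift would have carried three times the oscillations' in-band amplitude.
With these values a planted amplitude ratio of 1.5 yields a per-voxel ALFF
contrast of roughly 1.26 (the shared noise floor dilutes the ratio) and a
per-voxel Cohen's d around 2.5 at n = 20 vs 18.

Group effects are planted **multiplicatively on the oscillation amplitude**
inside chosen regions — exactly the quantity ALFF measures, so the planted
ratio is directly interpretable. Gray-matter covariate maps are a baseline
(0.6) plus between-subject Gaussian noise (sd 0.05), with a fractional
reduction for one group inside an atrophy region when planted. Per-subject
brain masks are the full grid minus a random 5% thinning of the one-voxel
boundary shell, so the intersection mask is a genuine intersection.

Defaults mirror the emulated acquisition: TR = 3 s, 124 volumes, 20 vs 18
subjects. The default grid is 24×24×16 at 3 mm — a desk-scale stand-in for
a normalized EPI grid chosen so a full pipeline run takes seconds; the
acquisition-sized grid (64×64×28) is a configuration choice.

Everything is reproducible bit-for-bit from `(spec, seed)`: subject `i`
draws from `SeedSequence((seed, i))` (series) and `SeedSequence((seed, i, 1))`
(mask and gray matter), so adding subjects never changes earlier ones.

**What the generator does not emulate:** hemodynamic response shape, head
motion, cardiac/respiratory aliasing, scanner drift beyond the 1/f term,
spatial autocorrelation of the noise (voxels are independent until the
pipeline smooths), and anatomical structure in the masks. Passing tests
demonstrate the statistical machinery is correct and calibrated under the
stated noise model — not that preprocessing choices on real data are
innocuous.

## Numerical notes

* The sinusoid bank is evaluated in float32 (≈5× faster); its ~1e-7
  relative trig error is far below every noise source. All statistics are
  computed in float64.
* The Gaussian kernel is truncated at 6 sigma so the sampled impulse
  response follows the analytic Gaussian into the <1e-6 tail.
* Single-sided Parseval: with the `a_k` convention above,
  `sum(x²) = |X_0|²/nt + sum_{0<k<nt/2} a_k²·nt/2 (+ a_{nt/2}²·nt/4 for even
  nt)` — used as the oracle for the spectrum code.
* Constant (zero-variance) voxel series get ALFF 0 and are logged, not
  dropped from the mask.
* Cluster peak = voxel of maximum |t| within the cluster, reported in world
  mm via the affine; ties break to the smallest linear voxel index.
* Monte-Carlo fields are generated in chunks of 100 to bound memory; the
  chunk size does not affect the stream of random draws' reproducibility
  for a fixed seed.

## Problem sizes used in the shipped analyses

The numbered drivers under `analysis/` and the acceptance script run the
study-shaped cohort (20 vs 18, 124 volumes) on the 24×24×16 desk grid with
1000 Monte-Carlo iterations, 400 fresh null fields for the
family-wise-error check, and 50 seeded replicates for the planted-effect
recovery study — sizes chosen so the complete battery runs in minutes on
one CPU while keeping Monte-Carlo standard errors a few percent or less.

## Known limitations

* The cluster-extent threshold depends strongly on the analysis mask, the
  voxel size, and the smoothness; published extents from other masks (e.g.
  a 540 mm³ / 20-voxel extent) are not transferable and are not reproduced
  here — on this package's whole-grid desk mask the corrected thresholds
  are an order of magnitude larger (see `analysis/04_alphasim_threshold.py`).
* Smoothness is a declared input, not estimated from residuals.
* No permutation inference, FDR, TFCE, or Gaussian-random-field analytics;
  the Monte-Carlo extent procedure is the only correction offered.
* One covariate of interest (gray matter); arbitrary design matrices are
  out of scope.
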