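# Methods

## Scope and model

`falffkit` implements a resting-state BOLD analysis chain whose central
statistic is the fractional amplitude of low-frequency fluctuations (fALFF):
the ratio of square-root spectral power inside 0.01–0.08 Hz to square-root
power over the entire frequency range, computed per voxel and standardized by
the within-mask global mean. fALFF is self-normalizing — multiplying a series
by any positive constant leaves it unchanged — which makes it robust to
broadband amplitude differences between voxels and subjects; plain ALFF is
kept alongside it for comparison. Downstream, the package provides voxelwise
group inference with Monte-Carlo cluster-extent correction, ROC evaluation of
an ROI-mean biomarker, and seed-based functional connectivity with a
connectivity-change taxonomy.

The package assumes volumes are already spatially aligned on a common grid
(the synthetic generator produces them that way; real-data users must supply
pre-aligned NIfTI volumes). Slice timing, realignment and spatial
normalization are out of scope.

## Preprocessing

Two branches share the initial steps and then diverge:

- **Amplitude branch**: discard the first `n_discard` volumes (default 10,
  signal equilibration) → Gaussian smoothing (default FWHM 4 mm, σ =
  FWHM/2.3548 per axis in voxel units, kernel normalized to unit sum) →
  per-voxel linear detrend (least-squares intercept + slope). fALFF needs the
  broadband spectrum, so no band-pass is applied before it; the 0.01–0.08 Hz
  band enters through the fALFF numerator.
- **Connectivity branch**: discard → detrend → zero-phase band-pass
  (0.01–0.08 Hz) → nuisance regression → seed correlation. The band-pass
  precedes nuisance regression and both are recorded in the series
  provenance, which `fc_zmap` enforces.

The band-pass is a frequency-domain mask with half-gain shoulder bins — a
phase-insensitive filter by construction. Its contract: passband gain within
5% at band center, stopband gain ≤ 0.05 at twice the upper edge and at DC.
No windowing is applied before any FFT; with the synthetic generator's
exact-bin signals leakage is nil, and for real data this matches the common
practice of the toolchains this analysis style comes from (documented as a
limitation).

Motion QC: framewise displacement FD(i) = Σ|Δtrans| + r·Σ|Δrot| with head
radius r = 50 mm (configurable), FD(1) = 0, the mean taken over frames 2…t.
Subjects whose cumulative translation exceeds `trans_limit_mm` or rotation
exceeds `rot_limit_deg` on any axis are excluded; the default limits are
2.0 mm / 2.0°. (Source protocols state both 2.0 and 2.5 at different points;
the threshold is a config parameter so either convention can be run.)
Rotations are radians internally — the SPM `rp_*.txt` convention — and become
degrees only in the exclusion check and reports.

## Cluster-extent correction

`monte_carlo_cluster_null` follows the AlphaSim construction: per iteration,
fill the analysis mask with iid standard Gaussian noise, smooth to the
declared FWHM, re-standardize within the mask, threshold two-sidedly at the
voxel p, and record the maximum cluster size under the chosen neighborhood
(default 26-connectivity; the null and the data thresholding always share one
setting). The minimal surviving extent is

k_min(α) = (the ⌈(1−α)·n_iterations⌉-th order statistic of the maxima) + 1,

and data clusters survive only if strictly larger than k_min — the strict
reading of a "minimal cluster size > k" rule. This double conservatism is
deliberate; the null-calibration experiment (below) confirms the realized
family-wise error sits well under the nominal α. Positive and negative
clusters are formed separately for signed statistics and carry a sign field.
The null's smoothness defaults to the applied smoothing FWHM (4 mm) because
the true map smoothness is not estimated; a config override exists.
Consequently printed k_min values from other toolchains on other masks are
not expected to be numerically recoverable.

Cluster tables report sizes in voxels and mm³ (voxel volume from the affine
determinant), the in-cluster |stat| peak, and peak coordinates both as grid
indices and world mm (affine · (i,j,k,1)); ordering is by size then
lexicographic peak coordinate, so output is deterministic.

## Group statistics

Voxelwise one-way ANOVA (F, df = (k−1, N−k)) and pooled-variance (Student)
two-sample t-tests, two-sided; the variance assumption matches the SPSS-era
default of the source analyses. Degenerate voxels (zero within-group
variance) get p = 1 and are counted in a QC log rather than raising.
Cohort-table utilities reconstruct one-way ANOVA from per-group (n, mean, sd)
summaries — SS_between = Σ nᵢ(mᵢ−m̄)², SS_within = Σ (nᵢ−1)sᵢ² — and compute
Pearson chi-squared without continuity correction for contingency tables.

Overlap of two significance masks is summarized by |A∩B| as a percentage of
|A|, of |B| and of |A∪B| (inclusion–exclusion).

## ROI biomarker and ROC

The biomarker is the ROI-mean of the normalized fALFF map. The ROC sweep uses
"score > threshold ⇒ positive" over all distinct scores with ±∞ sentinels;
AUC is the trapezoidal area (equal to the tie-corrected Mann–Whitney
statistic). The standard error is Hanley–McNeil; the normal-approximation CI
is **not** clipped to [0, 1], matching the reporting convention of the
clinical software this mirrors (upper bounds slightly above 1 are printed as
such). The p-value against AUC = 0.5 uses the same SE. The cut-point
maximizes the Youden index, ties broken toward the lower threshold; the
selection rule is stated because "cut-off point" alone underdetermines it.
Pairwise scalar t-tests are reported raw, without multiplicity adjustment,
mirroring exploratory clinical reporting. All of this is wrapped in the
sklearn estimator `ROCBiomarker` (fit/predict, fitted attributes with
trailing underscores) so it composes with sklearn model selection.

## Seed connectivity and change taxonomy

Nuisance regressors: 6 motion parameters, CSF mean, WM mean, and (by default,
switchable) the global brain mean, each centered; constant columns are
dropped with a warning, rank deficiency is resolved by dropping collinear
columns. Residuals are OLS with an implicit intercept. Correlations are
clamped to |r| ≤ 1−1e−7 before z = atanh(r), so seed-internal voxels stay in
the map without infinities.

Per-group sign maps come from cluster-corrected one-sample t-tests on the
z-maps: voxels in surviving positive-t clusters are "positive", negative-t
"negative", all else "none". A significant A-vs-B difference is then
described as:

- same sign in both groups → `{sign}_increased` / `{sign}_decreased`, where
  *increased* means larger connectivity **magnitude** in A (for shared
  negative sign, a difference toward more-negative z is an increase) — the
  magnitude reading is the only one consistent with describing a more
  strongly anticorrelated default-mode region as "negative connectivity
  increased";
- different signs (including one "none") → `positive_change` /
  `negative_change`, pointing the direction the difference moves A relative
  to B;
- both "none" → unclassifiable (the voxel-level table marks it
  `unclassified`).

Labels are invariant to any common positive rescaling of the z-maps.

## Synthetic cohort generator

The generator emulates the acquisition and cohort structure of the study
design it is validated against: five groups SUC/SC/DR/WH/CON of
n = 11/10/8/11/13 (53 subjects), 240 volumes at TR 2 s, 3 mm isotropic grid
(desk-scale default 20³ voxels). Per voxel,

signal = baseline + slope·(t−t̄) + ε(t) + g·m(t),

with baseline 100, slope ~ N(0, 0.02/volume), white noise ε ~ N(0, 1), and a
band-limited component m(t) synthesized from exact DFT-bin frequencies inside
0.01–0.08 Hz (leakage-free, analytically accountable in-band energy),
normalized to unit RMS and scaled by `inband_rms` (default 1) times the
owning region's per-group gain g. Regions with nonzero `coupling_to_seed` c
mix a common band-limited seed signal: m = c·s + √(1−c²)·own, giving in-band
correlation c with the designated seed region.

Default phantom layout (20³ grid): a 64-voxel "BA17-like" cube with gain 2.0
in SUC and DR (the designed biomarker effect; no published effect size
exists, so the gain is chosen for testability — it yields near-complete
ROC separation at full series length, deliberately stronger than clinical
reality), which is also the seed (c = 1 in all groups); a 64-voxel near-seed
region with c = 0.7 in SUC vs 0.25 in SC/CON; a 64-voxel distal
("default-mode-like") region with c = −0.5 in SUC only; and small CSF/WM
stand-in regions for nuisance regression. Motion traces are reflecting random
walks (step sd 0.18 mm / 0.18°, bound ±1.8) tuned to give mean FD ≈ 0.8 mm —
the level of the emulated cohort's patient groups — while keeping every
subject under the 2.0 mm/2.0° exclusion, mirroring a cohort of analyzable
subjects. The entire cohort is a pure function of the design (seeds derived
from `rng_seed` via SeedSequence); ground truth is written as a JSON sidecar
next to the NIfTI/rp-file/TSV outputs.

What the generator does **not** emulate: hemodynamic response shape, scanner
artifacts, slice-timing structure, spatial autocorrelation of the noise
(spatial structure enters only through smoothing and the designed couplings),
non-Gaussian physiological noise, and realistic motion. Passing recovery
tests therefore demonstrate correctness of the computation chain under its
own assumptions, not clinical performance on real data.

One emergent interaction worth knowing: smoothing averages neighboring
series, and within a coupled region the shared component survives averaging
while independent components cancel, so group-varying coupling slightly
raises smoothed in-band amplitude in that group. The five-group fALFF ANOVA
can therefore legitimately flag strongly coupled regions as well as
gain-elevated ones; this is a real consequence of the designed group
differences, not a false positive.

## Validation experiments (`falffkit.experiments`)

Problem sizes are the package's own defaults, chosen to keep each experiment
in the minutes range on one CPU: 20³ grid, 120-volume series, the main
two-group contrast n = 11 vs 13, Monte-Carlo nulls at 1000 iterations.

- **Null calibration**: 200 cohorts with all gains 1 and couplings 0; the
  fraction producing any surviving cluster at nominal α = 0.05 is the
  realized family-wise error (observed ≈ 0, comfortably under the 0.10
  acceptance bound — the order-statistic-plus-one k_min and strict survival
  make the procedure conservative).
- **Amplitude recovery**: per seed, success = a surviving cluster covers
  ≥ 80% of the true gain-2 region and ROI-mean fALFF separates the groups
  with AUC ≥ 0.9.
- **Connectivity recovery**: per seed, success = the affected group's sign
  map labels near-seed positive and distal negative (majorities), the
  control group's distal region stays unlabeled, and ≥ 90% of labeled
  difference voxels carry the designed taxonomy labels
  (`positive_increased`/`positive_change` near the seed, `negative_change`
  distally).

## Numerical choices and edge cases

- The DC bin is excluded from both fALFF sums ("entire frequency range" read
  as (0, Nyquist]); detrended series carry no meaningful DC, and including it
  would make the ratio depend on numerical detrend residue.
- Band-edge membership is inclusive with a 1e−12 guard against float
  rounding of bin centers.
- All-zero voxel series yield fALFF 0 and a QC count instead of raising, so
  cohort runs survive degenerate mask-edge voxels.
- Monte-Carlo smoothing with σ < 0.1 voxel on every axis is treated as no
  smoothing (warning), since the discrete kernel degenerates.
- TR comes from config with the NIfTI header as fallback; a >1% mismatch
  logs a warning. Masks must be strictly {0,1}-valued and share the cohort
  grid; no orientation-flipping heuristics are applied.
- Determinism: every stochastic component (generator, Monte-Carlo null,
  experiment seeds) is driven by explicit integer seeds; reruns are
  bit-identical.

## Known limitations

- The Monte-Carlo null assumes the declared FWHM equals the map smoothness;
  no smoothness estimation is performed.
- No window function before FFTs; spectral leakage on real (non-bin-aligned)
  data slightly blurs the band edges.
- The Hanley–McNeil CI and its p-value are large-sample approximations; at
  n ≈ 10 per group they are indicative, not exact.
- Global-signal regression is on by default for fidelity to the emulated
  pipeline; the practice is contested, and a flag disables it.
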