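# falffkit

A tested, reusable implementation of a resting-state fMRI analysis chain
built around the **fractional amplitude of low-frequency fluctuations
(fALFF)** as a regional biomarker, with seed-based functional connectivity
as the follow-up analysis. It is aimed at researchers who want to run — or
audit — this style of analysis end to end: temporal preprocessing and motion
QC, voxelwise amplitude statistics, Monte-Carlo cluster-extent correction,
ROC evaluation of an ROI-mean biomarker, and a connectivity-change taxonomy.
Because studies of this kind rarely deposit raw images, the package ships a
synthetic BOLD cohort generator with known ground truth, so every stage is
verifiable without external data.

## The statistics at the core

For a voxel time course $x(t)$ sampled at repetition time $TR$, the one-sided
DFT amplitude $a(f_k) = \sqrt{P(f_k)}$ is computed per frequency bin
($f_k = k/(N \cdot TR)$). Then

- **ALFF** $= \operatorname{mean}\{a(f_k): 0.01 \le f_k \le 0.08\ \mathrm{Hz}\}$,
- **fALFF** $= \sum_{band} a(f_k) \big/ \sum_{f_k>0} a(f_k) \in [0, 1]$,

and each subject's fALFF map is divided by its global (within-brain-mask)
mean. Group inference uses voxelwise one-way ANOVA and pooled-variance
two-sample t-tests, corrected for multiple comparisons by an AlphaSim-style
Monte-Carlo null: smooth Gaussian fields are simulated on the mask,
thresholded two-sidedly at the voxel-level p, and the minimal surviving
cluster extent $k_{min}(\alpha)$ is taken from the upper order statistics of
the per-iteration maximum cluster size. The ROI-mean fALFF is evaluated as a
classifier via the ROC curve, trapezoidal AUC with Hanley–McNeil standard
error, and the Youden cut-point. Seed connectivity is Pearson correlation of
each voxel with the seed-mean course after band-pass (0.01–0.08 Hz) and
nuisance regression (6 motion parameters, CSF, WM, global signal), Fisher
z-transformed; group differences are described with a six-label taxonomy
(`positive_increased`, `positive_decreased`, `negative_increased`,
`negative_decreased`, `positive_change`, `negative_change`) anchored on
per-group one-sample t sign maps.

## Worked example

Simulate the default five-group cohort (SUC/SC/DR/WH/CON, n = 11/10/8/11/13,
240 volumes, TR 2 s, 3 mm grid) and run every stage:

```sh
$ falffkit simulate-cohort --out demo --seed 7
wrote 53 subjects to demo
$ printf 'cohort_dir: demo\nout_dir: demo_out\n' > demo.yaml
$ falffkit run-all --config demo.yaml
{
  "n_retained": 53,
  "k_min": 26,
  "anova_clusters": 2,
  "roc": {
    "SUC_vs_CON": { "auc": 1.0, "cut": 1.3444168483853125 },
    "SUC_vs_SC":  { "auc": 1.0, "cut": 1.338919675776936 }
  }
}
```

Reading this output: all 53 subjects pass the 2.0 mm / 2.0° motion screen
(mean framewise displacement ≈ 0.78 mm by design); the Monte-Carlo null at
4 mm smoothness sets the minimal surviving cluster extent to 26 voxels
(702 mm³); the five-group fALFF ANOVA recovers 2 clusters — the designed
"BA17-like" amplitude region (peak at world (30, 24, 24) mm, its true
location) plus the coupled distal region; and the ROI-mean fALFF separates
the seizure-uncontrolled group from controls and from seizure-controlled
patients completely (AUC 1.0 at the default gain-2 effect — the generator's
effect size is chosen for testability, not clinical realism, where reported
AUCs are nearer 0.85). `demo_out/` contains the cluster tables (TSV, mm³,
world coordinates), the ROC report with confidence intervals and confusion
counts, per-pair connectivity-change tables, and the motion-QC log.
Pair directions in filenames are alphabetical: in `fc_changes_CON_vs_SUC.tsv`
group A is CON, so `positive_decreased` there means the connectivity is
larger in SUC.

The same stages are available as a library — sklearn-style transformers
(`BoldPreprocessor`, `FALFFExtractor`, `SeedConnectivity`), a classifier
(`ROCBiomarker` with fitted `auc_`, `ci_`, `cutpoint_`, `sensitivity_`,
`specificity_`), and plain functions for the statistics
(`voxelwise_anova`, `monte_carlo_cluster_null`, `corrected_significance`,
`summary_stat_anova`, `contingency_chi2`, `overlap_stats`, ...).

## Layout

- `src/falffkit/cohort.py` — synthetic cohort generator and ground truth
- `src/falffkit/preprocess.py` — discard, FD/motion QC, detrend, band-pass, smoothing
- `src/falffkit/falff.py` — ALFF/fALFF spectra, maps, global-mean normalization
- `src/falffkit/voxelstats.py` — ANOVA/t maps, Monte-Carlo cluster null, overlap, table stats
- `src/falffkit/roi_biomarker.py` — ROI means, ROC/AUC/CI, cut-points
- `src/falffkit/connectivity.py` — nuisance regression, seed maps, sign maps, taxonomy
- `src/falffkit/io.py`, `cli.py` — NIfTI/rp-text/TSV I/O, config, pipeline, CLI
- `src/falffkit/experiments.py` — the simulation studies used by tests and acceptance
- `docs/methods.md` — models, parameters, numerical choices, limitations
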