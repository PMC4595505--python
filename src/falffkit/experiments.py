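"""Simulation studies validating the pipeline against its own ground truth.

These experiments run the full analysis chain on synthetic cohorts and
measure its operating characteristics: family-wise false-positive rate under
the null, recovery of an injected region-amplitude effect (cluster overlap
and ROI-biomarker AUC), and recovery of designed seed-coupling patterns
(sign labels and change taxonomy).  Problem sizes default to a 20^3 grid
with 120-volume series and the study's main two-group contrast (n = 11 vs
13), which keeps each experiment in the minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import connectivity as fc
from .cohort import CohortDesign, build_phantom_masks, simulate_subject_bold
from .falff import amplitude_map, normalize_global_mean
from .preprocess import (BandSpec, MotionTrace, bandpass_filter, detrend_linear,
                         discard_initial_volumes, smooth_gaussian)
from .roi_biomarker import ROISample, roc_auc, roc_curve, roi_mean
from .voxelstats import corrected_significance, monte_carlo_cluster_null, voxelwise_ttest

TWO_GROUP = {"SUC": 11, "CON": 13}


def _experiment_design(**overrides) -> CohortDesign:
    return CohortDesign(**{"n_volumes": 120, **overrides})


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n).astype(np.int64) % (2**31)


def falff_branch_map(rec, brain, fwhm_mm=4.0, n_discard=10, band=BandSpec()):
    """Amplitude-branch preprocessing + normalized fALFF map for one subject."""
    pre = discard_initial_volumes(rec.bold, n_discard)
    pre = smooth_gaussian(pre, fwhm_mm)
    pre = detrend_linear(pre, brain)
    return normalize_global_mean(amplitude_map(pre, brain, band, "fALFF"))


def fc_branch_zmap(rec, brain, rois, n_discard=10, band=BandSpec(),
                   include_global=True, seed_region="ba17"):
    """Connectivity-branch preprocessing + seed z-map for one subject."""
    pre = discard_initial_volumes(rec.bold, n_discard)
    pre = detrend_linear(pre, brain)
    pre = bandpass_filter(pre, band)
    motion = MotionTrace(rec.motion.translations[n_discard:],
                         rec.motion.rotations[n_discard:])
    nuis = fc.build_nuisance(motion, pre, rois["csf"], rois["wm"], brain, include_global)
    pre = fc.regress_nuisance_series(pre, nuis)
    ts = fc.seed_timecourse(pre, rois[seed_region])
    return fc.fc_zmap(pre, ts, brain, seed_region)


def _two_group_cohort(design, brain, rois, seed, want_zmaps=False):
    seeds = _child_seeds(seed, sum(TWO_GROUP.values()))
    maps, samples, zmaps = {}, [], {}
    i = 0
    for g, n in TWO_GROUP.items():
        for _ in range(n):
            rec = simulate_subject_bold(design, g, int(seeds[i]))
            i += 1
            amap = falff_branch_map(rec, brain)
            maps.setdefault(g, []).append(amap)
            samples.append(ROISample(f"s{i}", g, roi_mean(amap, rois["ba17"])))
            if want_zmaps:
                zmaps.setdefault(g, []).append(fc_branch_zmap(rec, brain, rois))
    return maps, samples, zmaps


def null_familywise_error(n_cohorts: int = 200, seed: int = 0,
                          n_iterations: int = 1000) -> dict:
    """Fraction of no-effect cohorts yielding any surviving cluster at alpha 0.05.

    The cohorts use the study acquisition conditions but all region gains at 1
    and couplings at 0, so every surviving cluster is a family-wise false
    positive of the corrected two-sample comparison.
    """
    design = _experiment_design(region_specs=[])
    brain, rois_ = build_phantom_masks(design)
    rois = {"ba17": brain}  # ROI irrelevant under the null
    null = monte_carlo_cluster_null(brain, 4.0, 0.05, n_iterations, seed=seed)
    cohort_seeds = _child_seeds(seed + 1, n_cohorts)
    hits = 0
    for cs in cohort_seeds:
        maps, _, _ = _two_group_cohort(design, brain, rois, int(cs))
        tmap = voxelwise_ttest(maps["SUC"], maps["CON"], brain)
        _, sig = corrected_significance(tmap, 0.05, null, 0.05)
        hits += int(sig.any())
    return {"fwer": hits / n_cohorts, "n_cohorts": n_cohorts,
            "k_min": null.k_min(0.05)}


def amplitude_recovery(n_seeds: int = 20, seed: int = 0,
                       n_iterations: int = 1000) -> dict:
    """Recovery of the designed region-amplitude elevation (gain 2, n=11 vs 13).

    Success per cohort: a surviving cluster covers >= 80% of the true region
    AND the ROI-mean fALFF classifies the groups with AUC >= 0.9.
    """
    design = _experiment_design()
    brain, rois = build_phantom_masks(design)
    true_region = rois["ba17"].data
    null = monte_carlo_cluster_null(brain, 4.0, 0.05, n_iterations, seed=seed)
    cohort_seeds = _child_seeds(seed + 2, n_seeds)
    overlaps, aucs, successes = [], [], 0
    for cs in cohort_seeds:
        maps, samples, _ = _two_group_cohort(design, brain, rois, int(cs))
        tmap = voxelwise_ttest(maps["SUC"], maps["CON"], brain)
        _, sig = corrected_significance(tmap, 0.05, null, 0.05)
        overlap = (sig & true_region).sum() / true_region.sum()
        auc = roc_auc(roc_curve(samples, "SUC", "CON"))
        overlaps.append(overlap)
        aucs.append(auc)
        successes += int(overlap >= 0.8 and auc >= 0.9)
    return {"success_rate": successes / n_seeds, "mean_overlap": float(np.mean(overlaps)),
            "mean_auc": float(np.mean(aucs)), "n_seeds": n_seeds}


def fc_pattern_recovery(n_seeds: int = 20, seed: int = 0,
                        n_iterations: int = 1000) -> dict:
    """Recovery of the designed connectivity pattern and its change taxonomy.

    Success per cohort: the affected group's sign map labels the near-seed
    region positive and the distal region negative (majorities), the control
    group's distal region stays unlabeled, and the group-difference taxonomy
    marks near-seed voxels positive_increased/positive_change and distal
    voxels negative_change (>= 90% of labeled voxels, both regions nonempty).
    """
    design = _experiment_design()
    brain, rois = build_phantom_masks(design)
    near, distal = rois["near"].data, rois["distal"].data
    null = monte_carlo_cluster_null(brain, 4.0, 0.05, n_iterations, seed=seed)
    cohort_seeds = _child_seeds(seed + 3, n_seeds)
    successes = 0
    for cs in cohort_seeds:
        _, _, zmaps = _two_group_cohort(design, brain, rois, int(cs), want_zmaps=True)
        sm = {g: fc.group_sign_map(zmaps[g], 0.05, null) for g in zmaps}
        tmap, _, sig = fc.fc_group_compare(zmaps["SUC"], zmaps["CON"], brain, 0.05, null)
        changes = fc.change_table(sm["SUC"], sm["CON"], tmap, sig)
        signs_ok = ((sm["SUC"].sign[near] == "positive").mean() >= 0.5
                    and (sm["SUC"].sign[distal] == "negative").mean() >= 0.5
                    and (sm["CON"].sign[distal] == "none").mean() >= 0.5)
        if len(changes):
            in_near = changes[[near[i, j, k] for i, j, k in
                               zip(changes.i, changes.j, changes.k)]]
            in_dist = changes[[distal[i, j, k] for i, j, k in
                               zip(changes.i, changes.j, changes.k)]]
            taxonomy_ok = (
                len(in_near) > 0
                and in_near.label.isin(["positive_increased", "positive_change"]).mean() >= 0.9
                and len(in_dist) > 0
                and (in_dist.label == "negative_change").mean() >= 0.9)
        else:
            taxonomy_ok = False
        successes += int(signs_ok and taxonomy_ok)
    return {"success_rate": successes / n_seeds, "n_seeds": n_seeds}
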