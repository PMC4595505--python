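"""Readers/writers, pipeline configuration and end-to-end orchestration.

NIfTI-1 I/O goes through nibabel with float32 payloads (round-trips are
lossless at that precision).  Motion traces use the SPM ``rp_*.txt`` dialect:
six whitespace-separated columns per time point, translations in mm then
rotations in radians.  TR is taken from the config, with the NIfTI header as
fallback; a mismatch over 1% logs a warning (headers are unreliable).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import connectivity as fc
from . import roi_biomarker as rb
from . import voxelstats as vs
from .falff import amplitude_map, normalize_global_mean
from .preprocess import (BandSpec, BoldSeries, BrainMask, MotionTrace,
                         discard_initial_volumes, detrend_linear,
                         exceeds_motion_limits, framewise_displacement,
                         bandpass_filter, smooth_gaussian)

log = logging.getLogger("falffkit")


class FormatError(ValueError):
    """Typed error for malformed inputs."""


def read_bold(path: str | Path, tr_s: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: BOLD must be 4D, got {data.ndim}D")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_s is None:
        if header_tr <= 0:
            raise FormatError(f"{path}: no TR in header and none supplied")
        tr_s = header_tr
    elif header_tr > 0 and abs(header_tr - tr_s) > 0.01 * tr_s:
        log.warning("%s: header TR %.3fs differs from configured %.3fs; using config",
                    path, header_tr, tr_s)
    return BoldSeries(data.astype(float), img.affine, tr_s, provenance=["load"])


def write_bold(series: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (series.tr_s,))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D, got {data.ndim}D")
    vals = np.unique(data)
    if not np.isin(vals, [0, 1]).all():
        bad = [v for v in vals if v not in (0, 1)][:5]
        raise FormatError(f"{path}: mask values must be 0/1, found {bad}")
    return BrainMask(data.astype(bool), img.affine)


def write_mask(mask: BrainMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.float32), mask.affine), str(path))


def write_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_motion(path: str | Path) -> MotionTrace:
    """SPM rp-file: 6 columns, translations (mm) then rotations (radians)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected 6"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from e
    if not rows:
        raise FormatError(f"{path}: empty motion file")
    arr = np.asarray(rows)
    return MotionTrace(arr[:, :3], arr[:, 3:])


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), np.hstack([motion.translations, motion.rotations]), fmt="%.8e")


# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end analysis (units in docstrings)."""

    cohort_dir: str = "."
    out_dir: str = "falffkit_out"
    tr_s: float = 2.0
    n_discard: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.08
    fwhm_mm: float = 4.0
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    voxel_p: float = 0.05
    alpha: float = 0.05
    n_iterations: int = 1000
    connectivity: int = 26
    null_fwhm_mm: float | None = None  # defaults to fwhm_mm
    roi_mask: str = "roi_ba17.nii"
    seed_mask: str = "roi_ba17.nii"
    csf_mask: str = "roi_csf.nii"
    wm_mask: str = "roi_wm.nii"
    brain_mask: str = "brain_mask.nii"
    include_global: bool = True
    roc_pairs: list = field(default_factory=lambda: [["SUC", "CON"], ["SUC", "SC"]])
    fc_groups: list = field(default_factory=lambda: ["SUC", "SC", "CON"])
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise FormatError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.low_hz, self.high_hz)


def _preprocess_falff_branch(series: BoldSeries, mask: BrainMask,
                             cfg: PipelineConfig) -> BoldSeries:
    out = discard_initial_volumes(series, cfg.n_discard)
    out = smooth_gaussian(out, cfg.fwhm_mm)
    return detrend_linear(out, mask)


def _preprocess_fc_branch(series: BoldSeries, mask: BrainMask,
                          cfg: PipelineConfig) -> BoldSeries:
    out = discard_initial_volumes(series, cfg.n_discard)
    out = detrend_linear(out, mask)
    return bandpass_filter(out, cfg.band)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """End-to-end analysis of a cohort directory; returns the result bundle.

    Stages: motion QC -> fALFF maps -> five-group ANOVA with Monte-Carlo
    cluster correction -> pairwise t-maps within the ANOVA mask -> ROI ROC
    reports -> seed connectivity with sign maps and change taxonomy.
    """
    cdir = Path(cfg.cohort_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(cdir / "cohort.tsv", sep="\t")
    brain = read_mask(cdir / cfg.brain_mask)
    roi = read_mask(cdir / cfg.roi_mask)
    qc_rows = []
    subjects = []  # (subject_id, group, series, motion)
    for _, row in table.iterrows():
        bold_path = cdir / row["bold_path"]
        motion_path = cdir / row["motion_path"]
        if not motion_path.exists():
            raise FormatError(f"missing motion file for subject {row['subject_id']}")
        if not bold_path.exists():
            raise FormatError(f"missing BOLD file for subject {row['subject_id']}")
        series = read_bold(bold_path, tr_s=cfg.tr_s)
        motion = read_motion(motion_path)
        fd, mean_fd = framewise_displacement(motion)
        excluded, rep = exceeds_motion_limits(motion, cfg.trans_limit_mm, cfg.rot_limit_deg)
        qc_rows.append({"subject_id": row["subject_id"], "group": row["group"],
                        "mean_fd_mm": mean_fd, "excluded": excluded, **rep})
        if not excluded:
            subjects.append((row["subject_id"], row["group"], series, motion))
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "motion_qc.tsv", sep="\t", index=False)
    log.info("motion QC: %d/%d subjects retained", len(subjects), len(table))

    # fALFF branch
    group_maps: dict[str, list] = {}
    roi_samples = []
    for sid, group, series, _ in subjects:
        pre = _preprocess_falff_branch(series, brain, cfg)
        amap = normalize_global_mean(amplitude_map(pre, brain, cfg.band, "fALFF"))
        group_maps.setdefault(group, []).append(amap)
        roi_samples.append(rb.ROISample(sid, group, rb.roi_mean(amap, roi)))

    null_fwhm = cfg.null_fwhm_mm if cfg.null_fwhm_mm is not None else cfg.fwhm_mm
    null = vs.monte_carlo_cluster_null(
        brain, null_fwhm, cfg.voxel_p, cfg.n_iterations, cfg.rng_seed, cfg.connectivity)
    log.info("cluster null: k_min(%.2f) = %d voxels", cfg.alpha, null.k_min(cfg.alpha))
    anova = vs.voxelwise_anova(group_maps, brain)
    anova_table, anova_sig = vs.corrected_significance(anova, cfg.voxel_p, null, cfg.alpha)
    write_map(anova.stat, brain.affine, out / "falff_anova_F.nii")
    anova_table.to_csv(out / "falff_anova_clusters.tsv", sep="\t", index=False)

    ttest_tables = {}
    if anova_sig.any():
        anova_mask = BrainMask(anova_sig, brain.affine)
        null_t = vs.monte_carlo_cluster_null(
            anova_mask, null_fwhm, cfg.voxel_p, cfg.n_iterations,
            cfg.rng_seed + 1, cfg.connectivity)
        for a, b in [(a, b) for a in group_maps for b in group_maps if a < b]:
            tmap = vs.voxelwise_ttest(group_maps[a], group_maps[b], anova_mask)
            ttab, _ = vs.corrected_significance(tmap, cfg.voxel_p, null_t, cfg.alpha)
            ttest_tables[(a, b)] = ttab
            ttab.to_csv(out / f"falff_t_{a}_vs_{b}_clusters.tsv", sep="\t", index=False)

    # ROI biomarker
    roc_reports = {}
    for pos, neg in cfg.roc_pairs:
        curve = rb.roc_curve(roi_samples, pos, neg)
        ci = rb.auc_ci(curve)
        cp = rb.youden_cutpoint(curve)
        cm = rb.sens_spec_at(roi_samples, pos, neg, cp["cut"])
        roc_reports[(pos, neg)] = {**ci, **cp, **cm}
    pd.DataFrame([
        {"positive": p, "negative": n,
         **{k: ([float(x) for x in v] if isinstance(v, tuple) else v)
            for k, v in rep.items()}}
        for (p, n), rep in roc_reports.items()
    ]).to_csv(out / "roi_roc.tsv", sep="\t", index=False)

    # FC branch
    csf = read_mask(cdir / cfg.csf_mask)
    wm = read_mask(cdir / cfg.wm_mask)
    seed = read_mask(cdir / cfg.seed_mask)
    zmaps: dict[str, list] = {}
    for sid, group, series, motion in subjects:
        if group not in cfg.fc_groups:
            continue
        pre = _preprocess_fc_branch(series, brain, cfg)
        nuis = fc.build_nuisance(MotionTrace(motion.translations[cfg.n_discard:],
                                             motion.rotations[cfg.n_discard:]),
                                 pre, csf, wm, brain, cfg.include_global)
        pre = fc.regress_nuisance_series(pre, nuis)
        ts = fc.seed_timecourse(pre, seed)
        zmaps.setdefault(group, []).append(fc.fc_zmap(pre, ts, brain, "seed"))

    sign_maps = {g: fc.group_sign_map(ms, cfg.voxel_p, null, cfg.alpha)
                 for g, ms in zmaps.items()}
    fc_tables = {}
    for a, b in [(a, b) for a in zmaps for b in zmaps if a < b]:
        tmap, ttab, sig = fc.fc_group_compare(zmaps[a], zmaps[b], brain,
                                              cfg.voxel_p, null, cfg.alpha)
        changes = fc.change_table(sign_maps[a], sign_maps[b], tmap, sig)
        fc_tables[(a, b)] = {"clusters": ttab, "changes": changes}
        ttab.to_csv(out / f"fc_t_{a}_vs_{b}_clusters.tsv", sep="\t", index=False)
        changes.to_csv(out / f"fc_changes_{a}_vs_{b}.tsv", sep="\t", index=False)

    provenance = {"config": dataclasses.asdict(cfg), "k_min": null.k_min(cfg.alpha),
                  "n_retained": len(subjects)}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return {"qc": qc, "roi_samples": roi_samples, "anova": anova,
            "anova_clusters": anova_table, "anova_sig": anova_sig,
            "ttest_clusters": ttest_tables, "roc": roc_reports,
            "sign_maps": sign_maps, "fc_tables": fc_tables, "null": null}
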