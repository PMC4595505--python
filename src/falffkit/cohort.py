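"""Synthetic resting-state BOLD cohorts with known ground truth.

The generator emulates the study conditions of a five-group resting-state
cohort (SUC/SC/DR/WH/CON, n = 11/10/8/11/13) of 240-volume, TR = 2 s series
on a common 3 mm grid.  Each voxel's series is

    baseline + linear drift + white Gaussian noise + band-limited fluctuation,

where the band-limited component is synthesized from exact DFT-bin
frequencies inside 0.01-0.08 Hz (leakage-free in-band energy) with RMS
``inband_rms`` scaled by the owning region's per-group gain.  Voxels of a
region with nonzero ``coupling_to_seed`` share a common band-limited signal
with the designated seed region at the specified sign and strength, so
seed-based connectivity has a known truth.

Motion traces are bounded (reflecting) random walks; they exist to exercise
framewise-displacement computation and exclusion logic, not to model
physiology.  The entire cohort is a pure function of the design: identical
designs reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BoldSeries, BrainMask, MotionTrace

DEFAULT_GROUP_SIZES = {"SUC": 11, "SC": 10, "DR": 8, "WH": 11, "CON": 13}


@dataclass
class RegionEffect:
    """A labeled ROI with per-group amplitude gain and seed-coupling strength."""

    region_id: str
    voxel_set: np.ndarray  # (n, 3) integer grid coordinates
    inband_gain: dict[str, float] = field(default_factory=dict)
    coupling_to_seed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxel_set = np.atleast_2d(np.asarray(self.voxel_set, dtype=int))
        if self.voxel_set.size == 0 or self.voxel_set.shape[1] != 3:
            raise ValueError(f"region {self.region_id}: voxel_set must be nonempty (n,3)")
        for g, c in self.coupling_to_seed.items():
            if not -1.0 <= c <= 1.0:
                raise ValueError(f"region {self.region_id}: coupling for {g} outside [-1,1]")
        for g, gain in self.inband_gain.items():
            if gain < 0:
                raise ValueError(f"region {self.region_id}: negative gain for {g}")

    def gain(self, group: str) -> float:
        return float(self.inband_gain.get(group, 1.0))

    def coupling(self, group: str) -> float:
        return float(self.coupling_to_seed.get(group, 0.0))


def _default_regions() -> list[RegionEffect]:
    """Phantom layout on the default 20^3 grid.

    ba17  : 4x4x4 visual-cortex stand-in; elevated in-band amplitude in the
            seizure-uncontrolled and drug-resistant groups; the seed region.
    near  : seed-adjacent region with strong positive seed coupling in SUC,
            weaker in the others.
    distal: default-mode-network stand-in, anticorrelated with the seed in SUC.
    csf/wm: nuisance-tissue stand-ins (no effect) for connectivity regression.
    """

    def cube(sl) -> np.ndarray:
        g = np.mgrid[sl]
        return g.reshape(3, -1).T

    return [
        RegionEffect(
            "ba17", cube(np.s_[8:12, 8:12, 8:12]),
            inband_gain={"SUC": 2.0, "DR": 2.0},
            coupling_to_seed={g: 1.0 for g in DEFAULT_GROUP_SIZES},
        ),
        RegionEffect(
            "near", cube(np.s_[8:12, 8:12, 13:17]),
            coupling_to_seed={"SUC": 0.7, "SC": 0.25, "CON": 0.25},
        ),
        RegionEffect(
            "distal", cube(np.s_[2:6, 2:6, 2:6]),
            coupling_to_seed={"SUC": -0.5},
        ),
        RegionEffect("csf", cube(np.s_[15:17, 3:5, 3:5])),
        RegionEffect("wm", cube(np.s_[15:17, 15:17, 3:5])),
    ]


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort; the cohort is a pure function of it."""

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    n_volumes: int = 240
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    region_specs: list[RegionEffect] = field(default_factory=_default_regions)
    seed_region: str = "ba17"
    baseline: float = 100.0
    noise_sd: float = 1.0
    inband_rms: float = 1.0
    drift_slope_sd: float = 0.02
    motion_sd_mm: float = 0.18
    motion_sd_deg: float = 0.18
    motion_bound_mm: float = 1.8
    motion_bound_deg: float = 1.8
    brain_margin: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 4")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed the discarded-volume count")
        if min(self.noise_sd, self.inband_rms, self.drift_slope_sd,
               self.motion_sd_mm, self.motion_sd_deg) < 0:
            raise ValueError("noise/amplitude/motion scales must be nonnegative")
        shape = np.asarray(self.grid_shape)
        seen: set[tuple[int, int, int]] = set()
        for reg in self.region_specs:
            if (reg.voxel_set < 0).any() or (reg.voxel_set >= shape).any():
                raise ValueError(f"region {reg.region_id!r} has voxels outside the grid")
            vox = {tuple(v) for v in reg.voxel_set}
            if vox & seen:
                raise ValueError(f"region {reg.region_id!r} overlaps another region")
            seen |= vox

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def region(self, region_id: str) -> RegionEffect:
        for reg in self.region_specs:
            if reg.region_id == region_id:
                return reg
        raise KeyError(region_id)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    bold: BoldSeries
    motion: MotionTrace
    truth: dict

    def __post_init__(self) -> None:
        if self.bold.n_volumes != self.motion.n_timepoints:
            raise ValueError("bold and motion must have equal time points")


# ---------------------------------------------------------------------------


def build_phantom_masks(design: CohortDesign) -> tuple[BrainMask, dict[str, BrainMask]]:
    """Brain mask (all regions plus a surrounding bulk) and one binary mask per region."""
    brain = np.zeros(design.grid_shape, dtype=bool)
    m = design.brain_margin
    brain[m:design.grid_shape[0] - m,
          m:design.grid_shape[1] - m,
          m:design.grid_shape[2] - m] = True
    rois: dict[str, BrainMask] = {}
    for reg in design.region_specs:
        roi = np.zeros(design.grid_shape, dtype=bool)
        roi[tuple(reg.voxel_set.T)] = True
        brain |= roi
        rois[reg.region_id] = BrainMask(roi, design.affine)
    return BrainMask(brain, design.affine), rois


def _bandlimited(rng: np.random.Generator, shape: tuple, n_t: int, tr_s: float) -> np.ndarray:
    """Unit-RMS random signals with energy only at exact DFT bins in 0.01-0.08 Hz."""
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    sel = (freqs >= 0.01 - 1e-12) & (freqs <= 0.08 + 1e-12)
    spec = np.zeros(shape + (freqs.size,), dtype=complex)
    k = int(sel.sum())
    spec[..., sel] = rng.standard_normal(shape + (k,)) + 1j * rng.standard_normal(shape + (k,))
    x = np.fft.irfft(spec, n=n_t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    """Fold a walk into [-bound, bound] by reflection."""
    if bound <= 0:
        return np.zeros_like(x)
    return np.abs((x + bound) % (4.0 * bound) - 2.0 * bound) - bound


def simulate_subject_bold(design: CohortDesign, group: str, subject_seed: int) -> SubjectRecord:
    """Simulate one subject's 4D BOLD series, motion trace and ground-truth record."""
    if group not in design.group_sizes:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(subject_seed)
    nx, ny, nz = design.grid_shape
    n_t = design.n_volumes
    t = np.arange(n_t, dtype=float)

    data = design.baseline + design.noise_sd * rng.standard_normal((nx, ny, nz, n_t))
    slope = rng.normal(0.0, design.drift_slope_sd, size=(nx, ny, nz))
    data += slope[..., None] * (t - (n_t - 1) / 2.0)

    seed_signal = _bandlimited(rng, (), n_t, design.tr_s)  # shared component
    gain_map = np.ones((nx, ny, nz))
    coupling_map = np.zeros((nx, ny, nz))
    truth: dict = {"group": group, "regions": {}}
    for reg in design.region_specs:
        ijk = tuple(reg.voxel_set.T)
        gain_map[ijk] = reg.gain(group)
        coupling_map[ijk] = reg.coupling(group)
        truth["regions"][reg.region_id] = {
            "inband_gain": reg.gain(group),
            "coupling_to_seed": reg.coupling(group),
            "n_voxels": int(reg.voxel_set.shape[0]),
        }

    own = _bandlimited(rng, (nx, ny, nz), n_t, design.tr_s)
    mix = coupling_map[..., None] * seed_signal + \
        np.sqrt(1.0 - coupling_map[..., None] ** 2) * own
    data += design.inband_rms * gain_map[..., None] * mix

    steps_t = rng.normal(0.0, design.motion_sd_mm, size=(n_t, 3))
    steps_r = rng.normal(0.0, design.motion_sd_deg, size=(n_t, 3))
    steps_t[0] = steps_r[0] = 0.0
    trans = _reflect(np.cumsum(steps_t, axis=0), design.motion_bound_mm)
    rot = np.radians(_reflect(np.cumsum(steps_r, axis=0), design.motion_bound_deg))

    bold = BoldSeries(data, design.affine, design.tr_s, provenance=["simulate"])
    return SubjectRecord(
        subject_id=f"sub-{group}-{subject_seed:08d}",
        group=group,
        bold=bold,
        motion=MotionTrace(trans, rot),
        truth=truth,
    )


def subject_seeds(design: CohortDesign) -> list[tuple[str, int]]:
    """Deterministic (group, seed) assignment derived from the design's rng_seed."""
    ss = np.random.SeedSequence(design.rng_seed)
    n = design.n_subjects
    seeds = ss.generate_state(n).astype(np.int64) % (2**31)
    out = []
    i = 0
    for group in design.group_sizes:  # insertion order is part of the contract
        for _ in range(design.group_sizes[group]):
            out.append((group, int(seeds[i])))
            i += 1
    return out


def simulate_cohort(
    design: CohortDesign, out_dir: str | Path | None = None
) -> tuple[list[SubjectRecord], BrainMask, dict[str, BrainMask], pd.DataFrame]:
    """Simulate the whole cohort; optionally write NIfTI/rp-text/TSV/truth files."""
    brain, rois = build_phantom_masks(design)
    records = [simulate_subject_bold(design, g, s) for g, s in subject_seeds(design)]
    for i, rec in enumerate(records):
        rec.subject_id = f"sub-{i:03d}-{rec.group}"
    rows = [{"subject_id": r.subject_id, "group": r.group, "bold_path": "", "motion_path": ""}
            for r in records]
    table = pd.DataFrame(rows, columns=["subject_id", "group", "bold_path", "motion_path"])

    if out_dir is not None:
        from . import io as fio  # local import: io pulls nibabel

        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            probe = out / ".write_probe"
            probe.touch()
            probe.unlink()
        except OSError as e:
            raise OSError(f"output directory {out} is not writable: {e}") from e
        fio.write_mask(brain, out / "brain_mask.nii")
        for rid, roi in rois.items():
            fio.write_mask(roi, out / f"roi_{rid}.nii")
        for i, rec in enumerate(records):
            bold_path = out / f"{rec.subject_id}_bold.nii"
            motion_path = out / f"rp_{rec.subject_id}.txt"
            fio.write_bold(rec.bold, bold_path)
            fio.write_motion(rec.motion, motion_path)
            table.loc[i, "bold_path"] = bold_path.name
            table.loc[i, "motion_path"] = motion_path.name
        table.to_csv(out / "cohort.tsv", sep="\t", index=False)
        truth = {rec.subject_id: rec.truth for rec in records}
        truth["_design"] = _design_to_jsonable(design)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return records, brain, rois, table


def _design_to_jsonable(design: CohortDesign) -> dict:
    d = dataclasses.asdict(design)
    d["region_specs"] = [
        {"region_id": r.region_id,
         "n_voxels": int(r.voxel_set.shape[0]),
         "inband_gain": r.inband_gain,
         "coupling_to_seed": r.coupling_to_seed}
        for r in design.region_specs
    ]
    return json.loads(json.dumps(d, default=lambda o: np.asarray(o).tolist()))
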