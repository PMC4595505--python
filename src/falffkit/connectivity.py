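"""Seed-based functional connectivity and the connectivity-change taxonomy.

Per subject: band-pass the series, regress out nuisance signals (6 motion
parameters, CSF mean, WM mean and optionally the global mean), correlate the
seed-region mean time course with every voxel, and Fisher-transform r to z.
Group-level one-sample t-tests on z-maps, cluster-corrected, classify every
voxel's connectivity to the seed as positive / negative / none; two-sample
t-tests between groups are then described with a six-label change taxonomy
(increase/decrease within a shared sign, or positive/negative change when the
two groups' signs differ), where "increased" refers to connectivity
magnitude within the shared sign.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BoldSeries, BrainMask, MotionTrace
from .voxelstats import ClusterNull, StatMap, corrected_significance, one_sample_ttest, voxelwise_ttest

R_CLAMP = 1.0 - 1e-7


@dataclass
class NuisanceSet:
    """Centered nuisance regressors (t x k) with unique column labels; intercept implied."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("column labels must be unique")


@dataclass
class FCMap:
    """Voxelwise seed correlation r and its Fisher z inside a mask."""

    r: np.ndarray
    z: np.ndarray
    seed_label: str
    mask: BrainMask
    qc: dict = field(default_factory=dict)


class Sign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


class ChangeLabel(str, enum.Enum):
    POSITIVE_INCREASED = "positive_increased"
    POSITIVE_DECREASED = "positive_decreased"
    NEGATIVE_INCREASED = "negative_increased"
    NEGATIVE_DECREASED = "negative_decreased"
    POSITIVE_CHANGE = "positive_change"
    NEGATIVE_CHANGE = "negative_change"


@dataclass
class ConnectivitySignMap:
    """Per-voxel seed-connectivity sign from a cluster-corrected one-sample t map."""

    sign: np.ndarray  # array of Sign values (object dtype), 'none' outside survivors
    source: dict


def build_nuisance(
    motion: MotionTrace,
    series: BoldSeries,
    csf_mask: BrainMask,
    wm_mask: BrainMask,
    brain_mask: BrainMask,
    include_global: bool = True,
) -> NuisanceSet:
    """Assemble the centered nuisance matrix: 6 motion + CSF + WM (+ global)."""
    n_t = series.n_volumes
    if motion.n_timepoints != n_t:
        raise ValueError("motion trace and series time points differ")
    cols = [motion.translations, motion.rotations]
    labels = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    for name, msk in (("csf", csf_mask), ("wm", wm_mask)):
        if msk.data.shape != series.data.shape[:3]:
            raise ValueError(f"{name} mask grid does not match the series")
        if not msk.data.any():
            raise ValueError(f"empty {name} mask")
        cols.append(series.data[msk.data].mean(axis=0)[:, None])
        labels.append(name)
    if include_global:
        cols.append(series.data[brain_mask.data].mean(axis=0)[:, None])
        labels.append("global")
    X = np.hstack(cols)
    X = X - X.mean(axis=0)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [lbl for lbl, k in zip(labels, keep) if not k]
        warnings.warn(f"dropping constant nuisance columns: {dropped}")
        X = X[:, keep]
        labels = [lbl for lbl, k in zip(labels, keep) if k]
    return NuisanceSet(X, labels)


def regress_nuisance(ts: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residual of ts (1D or (V,t)) against the nuisance set plus intercept.

    Rank-deficient designs drop collinear columns with a warning.
    """
    X = nuisance.regressors
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; dropping collinear columns")
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        X = X[:, np.sort(piv[:rank])]
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = np.atleast_2d(ts).T  # (t, V)
    Y = Y - Y.mean(axis=0)  # intercept
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return resid[0] if one_d else resid


def regress_nuisance_series(series: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Apply nuisance regression to every voxel of a 4D series."""
    shape = series.data.shape
    resid = regress_nuisance(series.data.reshape(-1, shape[3]), nuisance)
    return series.with_data(resid.reshape(shape), "nuisance")


def seed_timecourse(series: BoldSeries, seed_mask: BrainMask) -> np.ndarray:
    """Per-time-point mean over the seed voxels."""
    if seed_mask.data.shape != series.data.shape[:3]:
        raise ValueError("seed mask grid does not match the series")
    if not seed_mask.data.any():
        raise ValueError("empty seed mask")
    return series.data[seed_mask.data].mean(axis=0)


def fc_zmap(series: BoldSeries, seed_ts: np.ndarray, mask: BrainMask,
            seed_label: str = "seed") -> FCMap:
    """Pearson r of every in-mask voxel with the seed course, Fisher z-transformed.

    Requires band-pass and nuisance-regression provenance; zero-variance
    voxels get r = 0 and are counted in the QC log.
    """
    missing = [s for s in ("bandpass", "nuisance") if s not in series.provenance]
    if missing:
        raise ValueError(f"series not ready for FC; missing steps: {missing}")
    if mask.data.shape != series.data.shape[:3]:
        raise ValueError("mask grid does not match the series")
    x = series.data[mask.data]  # (V, t)
    s = np.asarray(seed_ts, dtype=float) - np.mean(seed_ts)
    s_norm = np.linalg.norm(s)
    xc = x - x.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(xc, axis=1)
    dead = (x_norm == 0) | (s_norm == 0)
    denom = np.where(dead, 1.0, x_norm * s_norm)
    r = (xc @ s) / denom
    r[dead] = 0.0
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    r3 = np.zeros(mask.data.shape)
    r3[mask.data] = r
    z3 = np.zeros(mask.data.shape)
    z3[mask.data] = np.arctanh(r)
    qc = {"zero_variance_voxels": int(dead.sum())} if dead.any() else {}
    return FCMap(r3, z3, seed_label, mask, qc)


def group_sign_map(
    zmaps: list[FCMap], voxel_p: float, cluster_null: ClusterNull, alpha: float = 0.05
) -> ConnectivitySignMap:
    """Cluster-corrected one-sample t on z-maps -> per-voxel connectivity sign."""
    if len(zmaps) < 2:
        raise ValueError("need at least 2 z-maps")
    mask = zmaps[0].mask
    for m in zmaps:
        if m.mask.data.shape != mask.data.shape:
            raise ValueError("z-maps on different grids")
    tmap = one_sample_ttest([m.z for m in zmaps], mask)
    _, sig = corrected_significance(tmap, voxel_p, cluster_null, alpha)
    # plain strings, not Sign members: numpy mangles str-subclass scalars
    sign = np.full(mask.data.shape, Sign.NONE.value, dtype=object)
    sign[sig & (tmap.stat > 0)] = Sign.POSITIVE.value
    sign[sig & (tmap.stat < 0)] = Sign.NEGATIVE.value
    return ConnectivitySignMap(sign, {"voxel_p": voxel_p, "k_min": cluster_null.k_min(alpha),
                                      "n_maps": len(zmaps)})


def fc_group_compare(
    zmaps_a: list[FCMap], zmaps_b: list[FCMap], mask: BrainMask,
    voxel_p: float, cluster_null: ClusterNull, alpha: float = 0.05,
) -> tuple[StatMap, pd.DataFrame, np.ndarray]:
    """Two-sample t on z-maps with cluster-extent correction (delegates to voxelstats)."""
    tmap = voxelwise_ttest([m.z for m in zmaps_a], [m.z for m in zmaps_b], mask)
    table, sig = corrected_significance(tmap, voxel_p, cluster_null, alpha)
    return tmap, table, sig


def classify_change(sign_a: Sign, sign_b: Sign, t_direction: str) -> ChangeLabel:
    """Describe a significant group-A-vs-group-B connectivity difference.

    Same sign in both groups: increased/decreased of that sign, where
    "increased" means larger connectivity magnitude in group A (for negative
    connectivity, a_greater in z-units means less negative, i.e. decreased).
    Different signs (including one 'none'): positive_change if the difference
    moves A toward positive relative to B, else negative_change.
    """
    sign_a, sign_b = Sign(sign_a), Sign(sign_b)
    if t_direction not in ("a_greater", "b_greater"):
        raise ValueError("t_direction must be 'a_greater' or 'b_greater'")
    if sign_a is Sign.NONE and sign_b is Sign.NONE:
        raise ValueError("no classifiable difference: both signs are 'none'")
    a_greater = t_direction == "a_greater"
    if sign_a is sign_b:
        if sign_a is Sign.POSITIVE:
            return ChangeLabel.POSITIVE_INCREASED if a_greater else ChangeLabel.POSITIVE_DECREASED
        return ChangeLabel.NEGATIVE_DECREASED if a_greater else ChangeLabel.NEGATIVE_INCREASED
    return ChangeLabel.POSITIVE_CHANGE if a_greater else ChangeLabel.NEGATIVE_CHANGE


def change_table(
    sign_map_a: ConnectivitySignMap,
    sign_map_b: ConnectivitySignMap,
    tmap: StatMap,
    sig: np.ndarray,
) -> pd.DataFrame:
    """Voxel-level change taxonomy over the significant-difference mask."""
    rows = []
    for ijk in np.argwhere(sig):
        ijk = tuple(int(v) for v in ijk)
        sa, sb = Sign(sign_map_a.sign[ijk]), Sign(sign_map_b.sign[ijk])
        if sa is Sign.NONE and sb is Sign.NONE:
            label = None  # difference without a significant sign in either group
        else:
            label = classify_change(sa, sb, "a_greater" if tmap.stat[ijk] > 0 else "b_greater")
        rows.append({"i": ijk[0], "j": ijk[1], "k": ijk[2],
                     "sign_a": sa.value, "sign_b": sb.value,
                     "t": float(tmap.stat[ijk]),
                     "label": label.value if label else "unclassified"})
    return pd.DataFrame(rows, columns=["i", "j", "k", "sign_a", "sign_b", "t", "label"])


class SeedConnectivity(BaseEstimator, TransformerMixin):
    """Transformer mapping preprocessed BoldSeries to seed-connectivity FCMaps.

    Expects series that are already band-passed and nuisance-regressed (use
    :class:`falffkit.preprocess.BoldPreprocessor` plus
    :func:`regress_nuisance_series`).
    """

    def __init__(self, seed_mask: BrainMask | None = None,
                 mask: BrainMask | None = None, seed_label: str = "seed"):
        self.seed_mask = seed_mask
        self.mask = mask
        self.seed_label = seed_label

    def fit(self, X=None, y=None):
        if self.seed_mask is None or self.mask is None:
            raise ValueError("seed_mask and mask are required")
        self.n_features_in_ = 0
        return self

    def _one(self, series: BoldSeries) -> FCMap:
        ts = seed_timecourse(series, self.seed_mask)
        return fc_zmap(series, ts, self.mask, self.seed_label)

    def transform(self, X):
        if isinstance(X, BoldSeries):
            return self._one(X)
        return [self._one(s) for s in X]
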