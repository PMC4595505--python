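"""Voxelwise group inference with Monte-Carlo cluster-extent correction.

The multiple-comparisons control follows the AlphaSim construction: simulate
smooth Gaussian null fields on the analysis mask, threshold them voxelwise,
record the maximum cluster size per iteration, and derive the minimal
surviving cluster extent k_min(alpha) from the upper order statistics of that
null distribution.  Cluster formation is two-sided at the voxel threshold,
with positive and negative clusters labeled separately; survival requires
size strictly greater than k_min.

Also provides cluster labeling/reporting in world coordinates, mask-overlap
summaries, and cohort-table statistics (one-way ANOVA from group summaries,
Pearson chi-squared for contingency tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .falff import AmplitudeMap
from .preprocess import BrainMask, smooth_map

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

CLUSTER_COLUMNS = ["cluster_id", "size_voxels", "size_mm3", "peak_stat",
                   "peak_voxel_ijk", "peak_world_xyz_mm", "sign"]


@dataclass
class StatMap:
    """Voxelwise statistic map (F or t) with matching p-values inside a mask."""

    stat: np.ndarray
    p: np.ndarray
    df: tuple
    mask: BrainMask
    kind: str  # anova_F | two_sample_t | one_sample_t
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stat.shape != self.p.shape or self.stat.shape != self.mask.data.shape:
            raise ValueError("stat, p and mask grids must match")
        if self.kind not in ("anova_F", "two_sample_t", "one_sample_t"):
            raise ValueError(f"unknown stat kind {self.kind!r}")


@dataclass
class ClusterNull:
    """Monte-Carlo null distribution of the maximum cluster size.

    k_min(alpha) is the ceil((1-alpha)*n_iterations)-th order statistic of the
    per-iteration maxima, plus one; clusters must exceed it strictly to
    survive.
    """

    voxel_p_threshold: float
    fwhm_mm: float
    n_iterations: int
    max_cluster_sizes: np.ndarray
    connectivity: int = 26
    grid_shape: tuple | None = None

    def k_min(self, alpha: float = 0.05) -> int:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        order = int(ceil((1.0 - alpha) * self.n_iterations))
        return int(np.sort(self.max_cluster_sizes)[order - 1]) + 1


@dataclass(frozen=True)
class OverlapResult:
    size_a: int
    size_b: int
    size_intersection: int

    @property
    def size_union(self) -> int:
        return self.size_a + self.size_b - self.size_intersection

    @property
    def pct_of_a(self) -> float:
        return 100.0 * self.size_intersection / self.size_a if self.size_a else 0.0

    @property
    def pct_of_b(self) -> float:
        return 100.0 * self.size_intersection / self.size_b if self.size_b else 0.0

    @property
    def pct_of_union(self) -> float:
        return 100.0 * self.size_intersection / self.size_union if self.size_union else 0.0


# ---------------------------------------------------------------------------
# voxelwise tests


def _stack(maps: list[AmplitudeMap] | list[np.ndarray], mask: BrainMask) -> np.ndarray:
    arrs = []
    for m in maps:
        a = np.asarray(m, dtype=float) if isinstance(m, np.ndarray) else m.data
        if a.shape != mask.data.shape:
            raise ValueError("map grid does not match mask grid")
        arrs.append(a[mask.data])
    return np.asarray(arrs)  # (n_subjects, V)


def voxelwise_anova(group_maps: dict[str, list], mask: BrainMask) -> StatMap:
    """Per-voxel one-way ANOVA across groups; df = (k-1, N-k)."""
    if len(group_maps) < 2:
        raise ValueError("need at least 2 groups")
    stacks = {}
    for g, maps in group_maps.items():
        if len(maps) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        for m in maps:
            if isinstance(m, AmplitudeMap) and not m.normalized:
                raise ValueError("amplitude maps must be normalized before group stats")
        stacks[g] = _stack(maps, mask)
    k = len(stacks)
    N = sum(s.shape[0] for s in stacks.values())
    grand = np.sum([s.sum(axis=0) for s in stacks.values()], axis=0) / N
    ssb = np.zeros_like(grand)
    ssw = np.zeros_like(grand)
    for s in stacks.values():
        gm = s.mean(axis=0)
        ssb += s.shape[0] * (gm - grand) ** 2
        ssw += ((s - gm) ** 2).sum(axis=0)
    df = (k - 1, N - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df[0]) / (ssw / df[1])
    degenerate = ~np.isfinite(F) | (ssb <= 1e-300)
    F = np.where(degenerate, 0.0, F)
    p = stats.f.sf(F, *df)
    p = np.where(degenerate, 1.0, p)
    stat3 = np.zeros(mask.data.shape)
    p3 = np.ones(mask.data.shape)
    stat3[mask.data] = F
    p3[mask.data] = p
    return StatMap(stat3, p3, df, mask, "anova_F",
                   qc={"degenerate_voxels": int(degenerate.sum())})


def voxelwise_ttest(maps_a: list, maps_b: list, mask: BrainMask) -> StatMap:
    """Two-sided pooled-variance (Student) two-sample t per voxel; t > 0 means a > b."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("each side needs at least 2 subjects")
    a = _stack(maps_a, mask)
    b = _stack(maps_b, mask)
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = (((a - a.mean(axis=0)) ** 2).sum(axis=0)
           + ((b - b.mean(axis=0)) ** 2).sum(axis=0)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / se
    zero_var = se == 0
    t = np.where(zero_var, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var, 1.0, p)
    stat3 = np.zeros(mask.data.shape)
    p3 = np.ones(mask.data.shape)
    stat3[mask.data] = t
    p3[mask.data] = p
    return StatMap(stat3, p3, (df,), mask, "two_sample_t",
                   qc={"zero_variance_voxels": int(zero_var.sum())})


def one_sample_ttest(maps: list, mask: BrainMask) -> StatMap:
    """Two-sided one-sample t against 0 per voxel (used for connectivity sign maps)."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    x = _stack(maps, mask)
    n = x.shape[0]
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = x.mean(axis=0) / se
    zero_var = se == 0
    t = np.where(zero_var, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(zero_var, 1.0, p)
    stat3 = np.zeros(mask.data.shape)
    p3 = np.ones(mask.data.shape)
    stat3[mask.data] = t
    p3[mask.data] = p
    return StatMap(stat3, p3, (n - 1,), mask, "one_sample_t",
                   qc={"zero_variance_voxels": int(zero_var.sum())})


# ---------------------------------------------------------------------------
# clusters


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def label_clusters(
    binary_map: np.ndarray,
    connectivity: int = 26,
    stat: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    sign: str = "",
) -> pd.DataFrame:
    """Connected components of a binary map as a deterministic cluster table.

    Rows are ordered by size (descending) then lexicographic peak coordinate;
    peak is the in-cluster extremum of |stat| (first voxel if no stat given).
    """
    binary_map = np.asarray(binary_map).astype(bool)
    labels, n = ndimage.label(binary_map, structure=_structure(connectivity))
    voxel_vol = 1.0
    if affine is not None:
        voxel_vol = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    rows = []
    for lab in range(1, n + 1):
        ijk = np.argwhere(labels == lab)
        if stat is not None:
            vals = np.abs(stat[tuple(ijk.T)])
            peak = ijk[int(np.argmax(vals))]
            peak_stat = float(stat[tuple(peak)])
        else:
            order = np.lexsort(ijk.T[::-1])
            peak = ijk[order[0]]
            peak_stat = float("nan")
        world = (np.asarray(affine) @ np.append(peak, 1.0))[:3] if affine is not None \
            else peak.astype(float)
        rows.append({
            "cluster_id": lab,
            "size_voxels": int(ijk.shape[0]),
            "size_mm3": ijk.shape[0] * voxel_vol,
            "peak_stat": peak_stat,
            "peak_voxel_ijk": tuple(int(v) for v in peak),
            "peak_world_xyz_mm": tuple(float(v) for v in world),
            "sign": sign or ("positive" if peak_stat >= 0 else "negative"),
        })
    rows.sort(key=lambda r: (-r["size_voxels"], r["peak_voxel_ijk"]))
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    table["cluster_id"] = np.arange(1, len(table) + 1)
    return table


def monte_carlo_cluster_null(
    mask: BrainMask,
    fwhm_mm: float = 4.0,
    voxel_p_threshold: float = 0.05,
    n_iterations: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> ClusterNull:
    """AlphaSim-style null: smooth Gaussian fields, two-sided voxel threshold,
    maximum cluster size per iteration."""
    if n_iterations < 100:
        raise ValueError("need at least 100 iterations")
    struct = _structure(connectivity)
    voxel_size = np.sqrt((mask.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm / (2.3548200450309493 * voxel_size)
    do_smooth = bool((sigma_vox >= 0.1).any()) and fwhm_mm > 0
    z_crit = stats.norm.isf(voxel_p_threshold / 2.0)
    rng = np.random.default_rng(seed)
    in_mask = mask.data
    maxima = np.zeros(n_iterations, dtype=int)
    for i in range(n_iterations):
        field3 = rng.standard_normal(mask.data.shape)
        if do_smooth:
            field3 = smooth_map(field3, fwhm_mm, voxel_size)
        vals = field3[in_mask]
        field3 = (field3 - vals.mean()) / vals.std()
        supra = np.zeros(mask.data.shape, dtype=bool)
        supra[in_mask] = np.abs(field3[in_mask]) > z_crit
        labels, n = ndimage.label(supra, structure=struct)
        if n:
            maxima[i] = np.bincount(labels.ravel())[1:].max()
    return ClusterNull(voxel_p_threshold, fwhm_mm if do_smooth else 0.0,
                       n_iterations, maxima, connectivity, tuple(mask.data.shape))


def corrected_significance(
    stat_map: StatMap,
    voxel_p_threshold: float,
    cluster_null: ClusterNull,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster-extent corrected inference: supra-threshold voxels form clusters
    (positive/negative separately for signed stats); clusters strictly larger
    than k_min(alpha) survive."""
    if cluster_null.grid_shape is not None and \
            tuple(cluster_null.grid_shape) != stat_map.mask.data.shape:
        raise ValueError("cluster null was computed on a different grid")
    k_min = cluster_null.k_min(alpha)
    conn = cluster_null.connectivity
    supra = (stat_map.p < voxel_p_threshold) & stat_map.mask.data
    tables = []
    if stat_map.kind == "anova_F":
        tables.append(label_clusters(supra, conn, stat_map.stat, stat_map.mask.affine,
                                     sign="positive"))
    else:
        tables.append(label_clusters(supra & (stat_map.stat > 0), conn, stat_map.stat,
                                     stat_map.mask.affine, sign="positive"))
        tables.append(label_clusters(supra & (stat_map.stat < 0), conn, stat_map.stat,
                                     stat_map.mask.affine, sign="negative"))
    nonempty = [t for t in tables if len(t)]
    table = pd.concat(nonempty, ignore_index=True) if nonempty \
        else pd.DataFrame(columns=CLUSTER_COLUMNS)
    table = table[table["size_voxels"] > k_min].reset_index(drop=True)
    table = table.sort_values(
        ["size_voxels", "peak_voxel_ijk"], ascending=[False, True]
    ).reset_index(drop=True)
    table["cluster_id"] = np.arange(1, len(table) + 1)
    sig = np.zeros(stat_map.mask.data.shape, dtype=bool)
    struct = _structure(conn)
    for signed_supra in ([supra] if stat_map.kind == "anova_F"
                         else [supra & (stat_map.stat > 0), supra & (stat_map.stat < 0)]):
        labels, n = ndimage.label(signed_supra, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] > k_min
        sig |= keep[labels]
    return table, sig


def overlap_stats(mask_a, mask_b) -> OverlapResult:
    """Intersection/union summary of two binary maps on the same grid."""
    a = np.asarray(mask_a) if isinstance(mask_a, np.ndarray) else mask_a.data
    b = np.asarray(mask_b) if isinstance(mask_b, np.ndarray) else mask_b.data
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    a = a.astype(bool)
    b = b.astype(bool)
    return OverlapResult(int(a.sum()), int(b.sum()), int((a & b).sum()))


# ---------------------------------------------------------------------------
# cohort-table statistics


def summary_stat_anova(ns, means, sds) -> tuple[float, float]:
    """One-way ANOVA reconstructed from per-group (n, mean, sd) summaries."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape):
        raise ValueError("ns, means, sds must have equal length")
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("standard deviations must be nonnegative")
    k = ns.size
    N = ns.sum()
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    if ssb <= 0:
        return 0.0, 1.0
    if ssw <= 0:
        return float("inf"), 0.0
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return float(F), float(stats.f.sf(F, k - 1, N - k))


def contingency_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) for an r x c count table."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
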