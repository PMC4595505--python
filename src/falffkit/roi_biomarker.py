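"""ROI-mean fALFF as a scalar biomarker: group statistics and ROC evaluation.

The ROC sweep uses the convention "score > threshold => positive call", with
thresholds at every distinct score plus +/-inf sentinels, so the curve always
starts at (0,0) and ends at (1,1).  AUC is the trapezoidal area (ties counted
one half, making it equal to the Mann-Whitney U statistic over n_pos*n_neg);
its standard error follows Hanley & McNeil, and the normal-approximation
confidence interval is deliberately NOT clipped to [0,1] (SPSS-style output).
The cut-point maximizes the Youden index (sensitivity + specificity - 1),
ties broken toward the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .falff import AmplitudeMap
from .preprocess import BrainMask
from .voxelstats import summary_stat_anova


@dataclass(frozen=True)
class ROISample:
    subject_id: str
    group: str
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite ROI value for {self.subject_id}")


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    positive_label: str
    n_pos: int
    n_neg: int


def roi_mean(amap: AmplitudeMap, roi: BrainMask) -> float:
    """Arithmetic mean of the map over the ROI voxels (intersected with the brain mask)."""
    if roi.data.shape != amap.data.shape:
        raise ValueError("ROI grid does not match map grid")
    sel = roi.data & amap.mask.data
    if not sel.any():
        raise ValueError("ROI is empty within the brain mask")
    if sel.sum() < roi.data.sum():
        import warnings

        warnings.warn("ROI extends outside the brain mask; using the intersection")
    return float(amap.data[sel].mean())


def scalar_group_stats(
    samples: list[ROISample], pairs: list[tuple[str, str]] | None = None
) -> dict:
    """One-way ANOVA across all groups plus Student two-sample t for requested pairs.

    Pairwise p-values are reported raw (no multiplicity adjustment), matching
    common clinical reporting of exploratory pairwise contrasts.
    """
    groups: dict[str, list[float]] = {}
    for s in samples:
        groups.setdefault(s.group, []).append(s.value)
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    ns = [len(v) for v in groups.values()]
    means = [float(np.mean(v)) for v in groups.values()]
    sds = [float(np.std(v, ddof=1)) for v in groups.values()]
    F, p = summary_stat_anova(ns, means, sds)
    out = {"anova_F": F, "anova_p": p, "pairwise": {}}
    for a, b in pairs or []:
        if a not in groups or b not in groups:
            raise ValueError(f"unknown group in pair ({a}, {b})")
        t, tp = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        out["pairwise"][(a, b)] = {"t": float(t), "p": float(tp)}
    return out


def _split_scores(samples, positive_group, negative_group):
    pos = np.array([s.value for s in samples if s.group == positive_group], dtype=float)
    neg = np.array([s.value for s in samples if s.group == negative_group], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"labels {positive_group!r}/{negative_group!r} not both present in samples"
        )
    return pos, neg


def roc_curve(
    samples: list[ROISample], positive_group: str, negative_group: str
) -> ROCCurve:
    """Threshold sweep over all distinct scores; positive call iff score > threshold."""
    pos, neg = _split_scores(samples, positive_group, negative_group)
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([pos, neg]))[::-1], [-np.inf]])
    sens = np.array([(pos > c).mean() for c in thresholds])
    fpr = np.array([(neg > c).mean() for c in thresholds])
    return ROCCurve(thresholds, sens, fpr, positive_group, pos.size, neg.size)


def roc_auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve (equals the tie-corrected rank-sum statistic)."""
    return float(np.trapezoid(curve.sensitivity, curve.one_minus_specificity))


def auc_ci(curve: ROCCurve, level: float = 0.95) -> dict:
    """AUC with Hanley-McNeil SE, unclipped normal CI, and p-value against AUC=0.5."""
    if curve.n_pos < 2 or curve.n_neg < 2:
        raise ValueError("need at least 2 samples per group for a CI")
    A = roc_auc(curve)
    q1 = A / (2.0 - A)
    q2 = 2.0 * A * A / (1.0 + A)
    var = (A * (1 - A) + (curve.n_pos - 1) * (q1 - A * A)
           + (curve.n_neg - 1) * (q2 - A * A)) / (curve.n_pos * curve.n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.isf((1.0 - level) / 2.0)
    p = 2.0 * stats.norm.sf(abs(A - 0.5) / se) if se > 0 else 0.0
    return {"auc": A, "se": se, "ci": (A - z * se, A + z * se), "p": float(p)}


def youden_cutpoint(curve: ROCCurve) -> dict:
    """Threshold maximizing sensitivity + specificity - 1 (ties -> lower threshold)."""
    j = curve.sensitivity - curve.one_minus_specificity
    finite = np.isfinite(curve.thresholds)
    if not finite.any():
        raise ValueError("degenerate curve: no finite threshold")
    jf = np.where(finite, j, -np.inf)
    best = np.flatnonzero(jf == jf.max())[-1]  # thresholds descend: last max = lowest cut
    return {
        "cut": float(curve.thresholds[best]),
        "sensitivity": float(curve.sensitivity[best]),
        "specificity": float(1.0 - curve.one_minus_specificity[best]),
        "youden_j": float(j[best]),
    }


def sens_spec_at(
    samples: list[ROISample], positive_group: str, negative_group: str, cut: float
) -> dict:
    """Confusion counts at a fixed cut (positive call iff value > cut)."""
    if not np.isfinite(cut):
        raise ValueError("cut must be finite")
    pos, neg = _split_scores(samples, positive_group, negative_group)
    tp = int((pos > cut).sum())
    fn = pos.size - tp
    fp = int((neg > cut).sum())
    tn = neg.size - fp
    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


class ROCBiomarker(BaseEstimator, ClassifierMixin):
    """Sklearn-style classifier wrapping the ROC biomarker evaluation.

    ``fit(X, y)`` takes scalar scores X (shape (n,) or (n,1)) and binary
    labels y; it computes the full ROC sweep, AUC with Hanley-McNeil CI and
    the Youden cut-point.  ``predict`` calls a sample positive iff its score
    exceeds the fitted cut.

    Fitted attributes: ``curve_``, ``auc_``, ``se_``, ``ci_``, ``p_value_``,
    ``cutpoint_``, ``sensitivity_``, ``specificity_``, ``classes_``.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("ROCBiomarker requires exactly 2 classes")
        pos_label, neg_label = self.classes_[1], self.classes_[0]
        samples = [ROISample(str(i), str(lbl), v) for i, (lbl, v) in enumerate(zip(y, X))]
        self.curve_ = roc_curve(samples, str(pos_label), str(neg_label))
        ci = auc_ci(self.curve_, self.ci_level)
        self.auc_ = ci["auc"]
        self.se_ = ci["se"]
        self.ci_ = ci["ci"]
        self.p_value_ = ci["p"]
        cp = youden_cutpoint(self.curve_)
        self.cutpoint_ = cp["cut"]
        self.sensitivity_ = cp["sensitivity"]
        self.specificity_ = cp["specificity"]
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float).reshape(-1) - self.cutpoint_

    def predict(self, X):
        pos = np.asarray(X, dtype=float).reshape(-1) > self.cutpoint_
        return np.where(pos, self.classes_[1], self.classes_[0])
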