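"""Temporal preprocessing and motion quality control for resting-state BOLD.

The preprocessing branch for amplitude analysis is fixed as
``discard -> smooth -> detrend`` (band-limited amplitude fractions must be
computed on broadband data); the connectivity branch additionally applies
``bandpass`` and then nuisance regression.  Every step appends its name to
the series' provenance list so downstream stages can enforce ordering.

Rotations are stored in radians throughout (the SPM ``rp_*.txt`` convention);
degrees appear only at the motion-exclusion check and in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class BoldSeries:
    """One subject's 4D BOLD signal grid plus acquisition metadata.

    data : float array, shape (x, y, z, t), arbitrary signal units
    affine : 4x4 voxel-to-world transform (mm)
    tr_s : repetition time in seconds
    provenance : ordered names of the operations already applied
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray, step: str) -> "BoldSeries":
        return BoldSeries(data, self.affine, self.tr_s, self.provenance + [step])


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: t x 3 translations (mm), t x 3 rotations (rad)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError(
                "translations and rotations must both be t x 3 with equal row counts"
            )

    @property
    def n_timepoints(self) -> int:
        return self.translations.shape[0]


@dataclass
class BrainMask:
    """Binary 3D mask with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no nonzero voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class BandSpec:
    """Frequency band of interest in Hz (default 0.01-0.08, the low-frequency band)."""

    low_hz: float = 0.01
    high_hz: float = 0.08

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    def validate_for(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if self.high_hz > nyquist + 1e-12:
            raise ValueError(
                f"band high {self.high_hz} Hz exceeds Nyquist {nyquist} Hz for TR {tr_s} s"
            )


# ---------------------------------------------------------------------------
# operations


def discard_initial_volumes(series: BoldSeries, n_discard: int = 10) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration scrub)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    if n_discard == 0:
        return replace(series, provenance=series.provenance + ["discard"])
    return series.with_data(series.data[..., n_discard:], "discard")


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Per-frame framewise displacement (mm) and its mean over frames 2..t.

    FD(i) = sum |delta translation| + r * sum |delta rotation (rad)|, FD(1)=0,
    rotations projected onto a sphere of radius ``head_radius_mm``.
    """
    if motion.n_timepoints < 2:
        raise ValueError("need at least 2 time points for FD")
    if head_radius_mm <= 0:
        raise ValueError("head radius must be positive")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + head_radius_mm * dr])
    return fd, float(fd[1:].mean())


def exceeds_motion_limits(
    motion: MotionTrace, trans_limit_mm: float = 2.0, rot_limit_deg: float = 2.0
) -> tuple[bool, dict]:
    """Flag a subject whose cumulative motion exceeds the translation/rotation limits."""
    if trans_limit_mm < 0 or rot_limit_deg < 0:
        raise ValueError("motion limits must be nonnegative")
    abs_t = np.abs(motion.translations)
    abs_r_deg = np.degrees(np.abs(motion.rotations))
    it = np.unravel_index(np.argmax(abs_t), abs_t.shape)
    ir = np.unravel_index(np.argmax(abs_r_deg), abs_r_deg.shape)
    report = {
        "max_translation_mm": float(abs_t[it]),
        "max_translation_axis": "xyz"[it[1]],
        "max_rotation_deg": float(abs_r_deg[ir]),
        "max_rotation_axis": ("pitch", "roll", "yaw")[ir[1]],
    }
    flag = report["max_translation_mm"] > trans_limit_mm or report["max_rotation_deg"] > rot_limit_deg
    return bool(flag), report


def detrend_linear(series: BoldSeries, mask: BrainMask) -> BoldSeries:
    """Remove the per-voxel least-squares line (intercept + slope * time) inside the mask."""
    if mask.data.shape != series.data.shape[:3]:
        raise ValueError("mask grid does not match series grid")
    t = np.arange(series.n_volumes, dtype=float)
    tc = t - t.mean()
    x = series.data[mask.data]  # (V, t)
    slope = x @ tc / (tc @ tc)
    resid = x - x.mean(axis=1, keepdims=True) - slope[:, None] * tc
    out = series.data.copy()
    out[mask.data] = resid
    return series.with_data(out, "detrend")


def bandpass_filter(series: BoldSeries, band: BandSpec) -> BoldSeries:
    """Zero-phase band-pass by DFT masking with soft (half-gain) edge bins.

    The filter is applied in the frequency domain, so it is phase-insensitive
    by construction; DC is always removed.
    """
    band.validate_for(series.tr_s)
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=series.tr_s)
    h = np.zeros_like(freqs)
    inband = (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    h[inband] = 1.0
    # soft raised-cosine shoulder one bin outside each edge
    idx = np.where(inband)[0]
    if idx.size == 0:
        raise ValueError("no DFT bin falls inside the band; series too short")
    if idx[0] - 1 > 0:  # never re-admit DC
        h[idx[0] - 1] = 0.5
    if idx[-1] + 1 < freqs.size:
        h[idx[-1] + 1] = 0.5
    spec = np.fft.rfft(series.data, axis=3)
    out = np.fft.irfft(spec * h, n=n, axis=3)
    return series.with_data(out, "bandpass")


def _smooth_array(data: np.ndarray, fwhm_mm: float, voxel_size_mm: np.ndarray) -> np.ndarray:
    sigma_vox = fwhm_mm / (FWHM_TO_SIGMA * np.asarray(voxel_size_mm, dtype=float))
    if data.ndim == 4:
        sigma = tuple(sigma_vox) + (0.0,)
    else:
        sigma = tuple(sigma_vox)
    return ndimage.gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0)


def smooth_gaussian(obj, fwhm_mm: float = 4.0):
    """Spatial Gaussian smoothing (kernel normalized to unit sum), volume-wise for 4D.

    ``fwhm_mm`` is converted per axis through the voxel size; sigma = FWHM/2.3548.
    Accepts a BoldSeries (returns BoldSeries) or a bare 3D array plus the
    module-level helper for maps.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if isinstance(obj, BoldSeries):
        sm = _smooth_array(obj.data, fwhm_mm, obj.voxel_size_mm)
        return obj.with_data(sm, "smooth")
    raise TypeError("smooth_gaussian expects a BoldSeries; use smooth_map for 3D maps")


def smooth_map(data: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Gaussian-smooth a 3D map in mm units."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    return _smooth_array(np.asarray(data, dtype=float), fwhm_mm, np.asarray(voxel_size_mm))


class BoldPreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer bundling the temporal preprocessing branch.

    Steps run in the fixed order discard -> smooth -> detrend -> band-pass;
    any step can be disabled.  ``transform`` accepts a single BoldSeries or a
    list of them and needs a brain mask for detrending.

    Parameters
    ----------
    n_discard : leading volumes to drop (default 10)
    fwhm_mm : Gaussian smoothing FWHM in mm, or None to skip
    detrend : remove the per-voxel linear trend
    band : BandSpec or None to skip band-pass (the amplitude branch skips it)
    mask : BrainMask used for detrending
    """

    def __init__(self, n_discard: int = 10, fwhm_mm: float | None = 4.0,
                 detrend: bool = True, band: BandSpec | None = None,
                 mask: BrainMask | None = None):
        self.n_discard = n_discard
        self.fwhm_mm = fwhm_mm
        self.detrend = detrend
        self.band = band
        self.mask = mask

    def fit(self, X=None, y=None):
        if self.detrend and self.mask is None:
            raise ValueError("detrending requires a mask")
        self.n_features_in_ = 0
        return self

    def _transform_one(self, series: BoldSeries) -> BoldSeries:
        out = discard_initial_volumes(series, self.n_discard)
        if self.fwhm_mm is not None:
            out = smooth_gaussian(out, self.fwhm_mm)
        if self.detrend:
            out = detrend_linear(out, self.mask)
        if self.band is not None:
            out = bandpass_filter(out, self.band)
        return out

    def transform(self, X):
        if isinstance(X, BoldSeries):
            return self._transform_one(X)
        return [self._transform_one(s) for s in X]
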