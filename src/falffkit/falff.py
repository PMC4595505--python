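"""ALFF and fractional ALFF (fALFF) — the per-voxel low-frequency amplitude statistics.

For a detrended voxel time course the one-sided DFT amplitude (square root of
power) is computed per frequency bin.  ALFF is the mean amplitude across the
0.01-0.08 Hz bins; fALFF is the ratio of summed in-band amplitude to summed
amplitude over the entire frequency range.  The DC bin is excluded from both
sums: detrended signals carry no meaningful DC, and keeping it would make the
ratio depend on numerical detrend residue.  Band membership is inclusive at
both ends with a 1e-12 guard against float rounding of bin centers.

Voxelwise maps are standardized by dividing by the global (within-mask) mean,
so a normalized map averages exactly 1 inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BandSpec, BoldSeries, BrainMask

_EPS = 1e-12


@dataclass(frozen=True)
class FreqSpectrum:
    """One-sided amplitude spectrum: sqrt(power) per DFT bin, bins from 0 Hz."""

    freqs_hz: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs_hz.shape != self.amplitude.shape:
            raise ValueError("freqs and amplitude must have equal length")
        if self.freqs_hz[0] != 0 or np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs must start at 0 and strictly increase")


@dataclass
class AmplitudeMap:
    """Per-voxel ALFF or fALFF values on the mask grid (0 outside the mask)."""

    data: np.ndarray
    kind: str  # "ALFF" | "fALFF"
    normalized: bool
    band: BandSpec
    mask: BrainMask
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ALFF", "fALFF"):
            raise ValueError("kind must be 'ALFF' or 'fALFF'")
        if self.data.shape != self.mask.data.shape:
            raise ValueError("map and mask grids differ")


def amplitude_spectrum(ts: np.ndarray, tr_s: float) -> FreqSpectrum:
    """One-sided DFT amplitude spectrum of a time series; bin spacing 1/(N*TR)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1 or ts.size < 8:
        raise ValueError("time series must be 1D with at least 8 points")
    amp = np.abs(np.fft.rfft(ts))
    freqs = np.fft.rfftfreq(ts.size, d=tr_s)
    return FreqSpectrum(freqs, amp)


def _band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    return (freqs >= band.low_hz - _EPS) & (freqs <= band.high_hz + _EPS)


def alff(ts: np.ndarray, tr_s: float, band: BandSpec = BandSpec()) -> float:
    """Mean sqrt-power over the in-band bins (band ends inclusive)."""
    spec = amplitude_spectrum(ts, tr_s)
    sel = _band_bins(spec.freqs_hz, band)
    if not sel.any():
        raise ValueError(
            f"no DFT bin inside [{band.low_hz}, {band.high_hz}] Hz "
            f"(bin spacing {spec.freqs_hz[1]:.6g} Hz)"
        )
    return float(spec.amplitude[sel].mean())


def falff(ts: np.ndarray, tr_s: float, band: BandSpec = BandSpec()) -> float:
    """In-band amplitude sum over full-range amplitude sum, DC excluded from both.

    All-zero series return 0.0 (degenerate voxels at mask edges must not abort
    a cohort run; callers count them in QC logs).
    """
    spec = amplitude_spectrum(ts, tr_s)
    total = spec.amplitude[1:].sum()  # DC bin excluded
    if total <= 0:
        return 0.0
    sel = _band_bins(spec.freqs_hz, band)
    sel[0] = False
    return float(spec.amplitude[sel].sum() / total)


def amplitude_map(
    series: BoldSeries,
    mask: BrainMask,
    band: BandSpec = BandSpec(),
    kind: str = "fALFF",
) -> AmplitudeMap:
    """Voxelwise ALFF/fALFF inside the mask; requires discard+detrend provenance."""
    missing = [s for s in ("discard", "detrend") if s not in series.provenance]
    if missing:
        raise ValueError(f"series not preprocessed; missing steps: {missing}")
    if mask.data.shape != series.data.shape[:3]:
        raise ValueError("mask grid does not match series grid")
    band.validate_for(series.tr_s)
    x = series.data[mask.data]  # (V, t)
    amp = np.abs(np.fft.rfft(x, axis=1))
    freqs = np.fft.rfftfreq(x.shape[1], d=series.tr_s)
    sel = _band_bins(freqs, band)
    out = np.zeros(mask.data.shape)
    qc: dict = {}
    if kind == "ALFF":
        out[mask.data] = amp[:, sel].mean(axis=1)
    elif kind == "fALFF":
        sel = sel.copy()
        sel[0] = False
        total = amp[:, 1:].sum(axis=1)
        dead = total <= 0
        total[dead] = 1.0
        vals = amp[:, sel].sum(axis=1) / total
        vals[dead] = 0.0
        if dead.any():
            qc["zero_signal_voxels"] = int(dead.sum())
        out[mask.data] = vals
    else:
        raise ValueError("kind must be 'ALFF' or 'fALFF'")
    return AmplitudeMap(out, kind=kind, normalized=False, band=band, mask=mask, qc=qc)


def normalize_global_mean(amap: AmplitudeMap) -> AmplitudeMap:
    """Divide every in-mask voxel by the in-mask mean (global-mean standardization)."""
    if amap.normalized:
        raise ValueError("map is already normalized")
    m = amap.data[amap.mask.data].mean()
    if m <= 0:
        raise ValueError("in-mask mean is zero; cannot normalize")
    out = amap.data.copy()
    out[amap.mask.data] /= m
    return AmplitudeMap(out, amap.kind, True, amap.band, amap.mask, dict(amap.qc))


class FALFFExtractor(BaseEstimator, TransformerMixin):
    """Transformer computing (optionally normalized) amplitude maps per subject.

    ``transform`` maps a list of preprocessed BoldSeries to a list of
    AmplitudeMap.  Parameters mirror :func:`amplitude_map`.
    """

    def __init__(self, mask: BrainMask | None = None, band: BandSpec = BandSpec(),
                 kind: str = "fALFF", normalize: bool = True):
        self.mask = mask
        self.band = band
        self.kind = kind
        self.normalize = normalize

    def fit(self, X=None, y=None):
        if self.mask is None:
            raise ValueError("a brain mask is required")
        self.n_features_in_ = 0
        return self

    def _one(self, series: BoldSeries) -> AmplitudeMap:
        amap = amplitude_map(series, self.mask, self.band, self.kind)
        return normalize_global_mean(amap) if self.normalize else amap

    def transform(self, X):
        if isinstance(X, BoldSeries):
            return self._one(X)
        return [self._one(s) for s in X]
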