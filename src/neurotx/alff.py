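"""Amplitude of low-frequency fluctuations (ALFF) from cleaned BOLD series.

Per voxel: linear detrend, optional nuisance regression, ideal (DFT boxcar)
bandpass to 0.01-0.08 Hz, then the one-sided amplitude spectrum
``a_k = 2|X_k|/N``. Raw ALFF is the *mean* of ``a_k`` over bins whose center
frequency lies in the band (inclusive edges), which makes the statistic
invariant to series length for a fixed band. Standardized ALFF (mALFF) is
raw ALFF divided by its in-mask mean, removing global scaling so group
contrasts act on relative amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, StatMap, TimeSeriesImage, VolumeGrid, log_stage

DEFAULT_BAND = (0.01, 0.08)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceSet:
    """Per-subject nuisance regressors: columns of a [t x k] matrix.

    Stands in for motion parameters, tissue-mean signals, and (optionally)
    the global mean signal; which columns are present is up to the caller.
    """

    regressors: np.ndarray | None = None
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.regressors is not None:
            reg = np.atleast_2d(np.asarray(self.regressors, dtype=float))
            if reg.ndim != 2:
                raise ValueError("regressors must be a 2D [t x k] matrix")
            self.regressors = reg
            if not self.names:
                self.names = tuple(f"reg{i}" for i in range(reg.shape[1]))

    @property
    def k(self) -> int:
        return 0 if self.regressors is None else self.regressors.shape[1]


@dataclass
class AlffMap:
    grid: VolumeGrid
    mask: BinaryMask
    raw_alff: np.ndarray
    standardized_alff: np.ndarray

    def __post_init__(self):
        if np.any(self.raw_alff[self.mask.inside] < 0):
            raise ValueError("raw ALFF must be nonnegative")


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (and mean) along the last axis."""
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    slope = (series * t_c).sum(axis=-1, keepdims=True) / (t_c ** 2).sum()
    return series - series.mean(axis=-1, keepdims=True) - slope * t_c


def regress_nuisance(series: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residuals of each series against the nuisance set plus intercept.

    With an empty nuisance set this reduces to mean-centering. A
    rank-deficient design raises, naming the collinear columns.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if nuisance.k == 0:
        return series - series.mean(axis=-1, keepdims=True)
    reg = nuisance.regressors
    if reg.shape[0] != n:
        raise ValueError("regressor rows must match time-series length")
    X = np.column_stack([np.ones(n), reg])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, ("intercept", *nuisance.names))
        raise ValueError(f"nuisance matrix is rank deficient; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(X, series.reshape(-1, n).T, rcond=None)
    resid = series.reshape(-1, n).T - X @ beta
    return resid.T.reshape(series.shape)


def _collinear_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Greedy scan for columns that add no rank; used only for error messages."""
    bad, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j] if j < len(names) else f"col{j}")
    return bad


def band_bins(n: int, tr: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Indices of one-sided DFT bins whose center frequency is in [low, high]."""
    freqs = np.fft.rfftfreq(n, d=tr)
    return np.flatnonzero((freqs >= low_hz) & (freqs <= high_hz))


def bandpass_filter(series: np.ndarray, tr: float,
                    low_hz: float = DEFAULT_BAND[0],
                    high_hz: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Ideal bandpass: zero every DFT coefficient outside [low_hz, high_hz]."""
    if low_hz >= high_hz:
        raise ValueError("band edges inverted (low_hz >= high_hz)")
    nyquist = 1.0 / (2.0 * tr)
    if high_hz >= nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist}")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    spec = np.fft.rfft(series, axis=-1)
    keep = np.zeros(spec.shape[-1], dtype=bool)
    keep[band_bins(n, tr, low_hz, high_hz)] = True
    spec = np.where(keep, spec, 0.0)
    return np.fft.irfft(spec, n=n, axis=-1)


def amplitude_spectrum(series: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectrum a_k = 2|X_k|/N along the last axis."""
    n = series.shape[-1]
    return 2.0 * np.abs(np.fft.rfft(series, axis=-1)) / n


def compute_alff(ts: TimeSeriesImage, nuisance: NuisanceSet | None = None,
                 band: tuple[float, float] = DEFAULT_BAND,
                 smoothing_fwhm_mm: float = 0.0) -> AlffMap:
    """Detrend, regress nuisance, bandpass, and average the in-band amplitude.

    The text order is honored: the series is bandpassed first and the
    spectrum of the filtered series is then averaged over the (same) band —
    redundant but harmless. Standardization divides by the in-mask mean.
    """
    nuisance = nuisance or NuisanceSet()
    series = ts.in_mask_series().astype(float)
    series = detrend_linear(series)
    series = regress_nuisance(series, nuisance)
    series = bandpass_filter(series, ts.tr_seconds, *band)
    spec = amplitude_spectrum(series)
    bins = band_bins(ts.n_timepoints, ts.tr_seconds, *band)
    if bins.size == 0:
        raise ValueError("no DFT bins fall inside the band")
    raw_vec = spec[:, bins].mean(axis=1)

    raw = np.zeros(ts.grid.shape)
    raw[ts.mask.inside] = raw_vec
    if smoothing_fwhm_mm > 0:
        raw = smooth_gaussian(raw, ts.grid, ts.mask, smoothing_fwhm_mm)
    mean_raw = raw[ts.mask.inside].mean()
    if mean_raw <= 0:
        raise ValueError("cannot standardize: in-mask mean ALFF is zero")
    std = np.zeros_like(raw)
    std[ts.mask.inside] = raw[ts.mask.inside] / mean_raw
    log_stage("alff", voxels=ts.mask.n_voxels, timepoints=ts.n_timepoints,
              band=band, fwhm=smoothing_fwhm_mm)
    return AlffMap(ts.grid, ts.mask, raw, std)


def smooth_gaussian(volume: np.ndarray, grid: VolumeGrid, mask: BinaryMask,
                    fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing with mask-aware edge renormalization.

    Smoothing is applied to ``volume * mask`` and divided by the smoothed
    mask so a constant map stays constant up to the mask boundary; voxels
    outside the mask are returned as zero.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        out = np.where(mask.inside, volume, 0.0)
        return out
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size
    num = ndimage.gaussian_filter(np.where(mask.inside, volume, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(mask.inside.astype(float), sigma_vox)
    out = np.zeros_like(num)
    ok = mask.inside & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out
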