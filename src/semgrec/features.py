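"""Time- and frequency-domain window features: MAV, RMS, MPF, MF.

Per window and channel the four classical EMG descriptors are computed:

* MAV, mean absolute value: (1/N) sum |x_i|
* RMS, root mean square: sqrt((1/N) sum x_i^2)
* MPF, mean power frequency: integral of f P(f) df over integral of P(f) df
* MF, median frequency: the frequency splitting spectral power in half

P(f) is a Welch estimate (256-sample Hamming segments, 50% overlap). The
28-column feature matrix (channel-major: ch1 MAV, RMS, MPF, MF, ch2 ...) feeds
the RBF-SVM baseline after per-column z-scoring fitted on training rows only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .segmentation import CLASS_CODES, WindowDataset

__all__ = ["PSDEstimate", "FeatureMatrix", "mav", "rms", "estimate_psd",
           "mpf", "mf", "featurize", "normalize", "FEATURE_NAMES"]

log = logging.getLogger(__name__)

FEATURE_NAMES = ("mav", "rms", "mpf", "mf")

_WELCH_NPERSEG = 256


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power density must be nonnegative")


@dataclass
class FeatureMatrix:
    values: np.ndarray                      # (n_windows, 4 * n_channels)
    labels: np.ndarray                      # (n_windows,) integer class codes
    columns: list[str] = field(default_factory=list)
    norm_params: dict | None = None         # {"mean": ..., "sd": ...} once normalized


def mav(x: np.ndarray) -> float:
    """Mean absolute value, (1/N) sum |x_i|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty series is undefined")
    return float(np.mean(np.abs(x)))


def rms(x: np.ndarray) -> float:
    """Root mean square, sqrt((1/N) sum x_i^2)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty series is undefined")
    return float(np.sqrt(np.mean(x ** 2)))


def estimate_psd(x: np.ndarray, fs: float) -> PSDEstimate:
    """Welch power spectral density, 256-sample Hamming segments, 50% overlap."""
    x = np.asarray(x, dtype=float)
    if x.size < _WELCH_NPERSEG:
        raise ValueError(f"series of length {x.size} shorter than one "
                         f"{_WELCH_NPERSEG}-sample Welch segment")
    freqs, power = sps.welch(x, fs=fs, window="hamming",
                             nperseg=_WELCH_NPERSEG, noverlap=_WELCH_NPERSEG // 2)
    return PSDEstimate(freqs=freqs, power=power)


def _total_power(psd: PSDEstimate) -> float:
    return float(np.trapezoid(psd.power, psd.freqs))


def mpf(psd: PSDEstimate) -> float:
    """Mean power frequency: power-weighted mean of the spectrum."""
    total = _total_power(psd)
    if total <= 0:
        raise ValueError("mean power frequency undefined for zero total power")
    return float(np.trapezoid(psd.freqs * psd.power, psd.freqs) / total)


def mf(psd: PSDEstimate) -> float:
    """Median frequency: smallest grid frequency whose cumulative trapezoidal
    power reaches half the total (left-continuous tie rule)."""
    total = _total_power(psd)
    if total <= 0:
        raise ValueError("median frequency undefined for zero total power")
    seg = 0.5 * np.diff(psd.freqs) * (psd.power[:-1] + psd.power[1:])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = 0.5 * total
    idx = int(np.searchsorted(cum, half * (1 - 1e-12), side="left"))
    return float(psd.freqs[min(idx, psd.freqs.size - 1)])


def featurize(ds: WindowDataset, fs: float) -> FeatureMatrix:
    """Per-window, per-channel [MAV, RMS, MPF, MF] in fixed channel-major order.

    A channel with zero total spectral power gets MPF = MF = 0 with a warning
    rather than aborting (degenerate all-zero windows can survive screening
    when the RMS floor is off).
    """
    if len(ds) == 0:
        raise ValueError("cannot featurize an empty dataset")
    n_ch = ds.windows[0].samples.shape[0]
    columns = [f"ch{c + 1}_{feat}" for c in range(n_ch) for feat in FEATURE_NAMES]
    rows = np.empty((len(ds), 4 * n_ch))
    for i, w in enumerate(ds.windows):
        for c in range(n_ch):
            x = w.samples[c]
            psd = estimate_psd(x, fs)
            if _total_power(psd) > 0:
                f_mean, f_med = mpf(psd), mf(psd)
            else:
                log.warning("zero-power channel %d in window %d; MPF/MF set to 0", c, i)
                f_mean = f_med = 0.0
            rows[i, 4 * c: 4 * c + 4] = (mav(x), rms(x), f_mean, f_med)
    labels = np.array([CLASS_CODES[w.label] for w in ds.windows], dtype=int)
    return FeatureMatrix(values=rows, labels=labels, columns=columns)


def normalize(fm: FeatureMatrix, fit_on: np.ndarray | None = None) -> FeatureMatrix:
    """Column z-score with moments fitted on ``fit_on`` row indices only.

    ``fit_on=None`` fits on all rows. Fitted moments are stored in
    ``norm_params`` so the identical affine map can be applied to held-out
    rows; training-subset columns come out with mean 0, sd 1.
    """
    idx = np.arange(fm.values.shape[0]) if fit_on is None else np.asarray(fit_on)
    if idx.size < 2:
        raise ValueError("need at least 2 rows to fit normalization")
    mean = fm.values[idx].mean(axis=0)
    sd = fm.values[idx].std(axis=0, ddof=0)
    zero_var = np.nonzero(sd == 0)[0]
    if zero_var.size:
        names = [fm.columns[j] if fm.columns else str(j) for j in zero_var]
        raise ValueError(f"zero-variance feature column(s) in fit subset: {names}")
    values = (fm.values - mean) / sd
    return FeatureMatrix(values=values, labels=fm.labels.copy(),
                         columns=list(fm.columns),
                         norm_params={"mean": mean, "sd": sd})
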