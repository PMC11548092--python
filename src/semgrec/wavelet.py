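"""Orthonormal Daubechies-2 wavelet transform and threshold denoising.

Implements the discrete wavelet transform with the 4-tap db2 filter pair,
periodized boundary handling, multi-level decomposition/reconstruction, and
universal-threshold shrinkage of the detail coefficients. Periodization keeps
the transform exactly orthonormal on even-length inputs, so soft thresholding
can only shrink signal energy; odd-length levels are padded by repeating the
final sample and trimmed on reconstruction.
"""
from __future__ import annotations

import numpy as np

__all__ = ["dwt", "idwt", "wavedec", "waverec", "universal_threshold", "denoise"]

_SQ3 = np.sqrt(3.0)
_DEN = 4.0 * np.sqrt(2.0)
#: db2 orthonormal scaling (low-pass) filter.
DB2_LO = np.array([(1 + _SQ3), (3 + _SQ3), (3 - _SQ3), (1 - _SQ3)]) / _DEN
#: Quadrature-mirror high-pass filter: g[k] = (-1)^k h[L-1-k].
DB2_HI = np.array([DB2_LO[3], -DB2_LO[2], DB2_LO[1], -DB2_LO[0]])


def _analysis_matrix_indices(n: int) -> np.ndarray:
    # rows: shifts by 2 of the 4-tap filter, wrapped periodically
    k = np.arange(n // 2)[:, None]
    m = np.arange(4)[None, :]
    return (2 * k + m) % n


def dwt(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One level of the periodized db2 transform.

    Returns (approximation, detail), each of length ``ceil(len(x)/2)``. An
    odd-length input is extended by one repeated sample first.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt expects a 1-D signal")
    if x.size < 2:
        raise ValueError("dwt needs at least 2 samples")
    if x.size % 2:
        x = np.concatenate([x, x[-1:]])
    idx = _analysis_matrix_indices(x.size)
    cols = x[idx]
    return cols @ DB2_LO, cols @ DB2_HI


def idwt(approx: np.ndarray, detail: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`dwt`; ``length`` is the pre-transform signal length."""
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape:
        raise ValueError("approximation/detail length mismatch")
    n = 2 * approx.size
    x = np.zeros(n)
    idx = _analysis_matrix_indices(n)
    # transpose of the orthonormal analysis map: scatter-add each row's taps
    np.add.at(x, idx, approx[:, None] * DB2_LO[None, :])
    np.add.at(x, idx, detail[:, None] * DB2_HI[None, :])
    return x[:length]


def wavedec(x: np.ndarray, levels: int) -> tuple[np.ndarray, list[np.ndarray], list[int]]:
    """Multi-level decomposition.

    Returns ``(approx, details, lengths)`` with details ordered coarse → fine
    and ``lengths[j]`` the signal length entering level ``j`` (needed to undo
    odd-length padding).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** levels:
        raise ValueError(
            f"signal of length {x.size} too short for {levels}-level decomposition"
        )
    details: list[np.ndarray] = []
    lengths: list[int] = []
    a = x
    for _ in range(levels):
        lengths.append(a.size)
        a, d = dwt(a)
        details.append(d)
    return a, details[::-1], lengths[::-1]


def waverec(approx: np.ndarray, details: list[np.ndarray], lengths: list[int]) -> np.ndarray:
    a = approx
    for d, n in zip(details, lengths):
        a = idwt(a, d, n)
    return a


def universal_threshold(finest_detail: np.ndarray, n: int) -> float:
    """Donoho-Johnstone universal threshold sigma*sqrt(2 ln N).

    The noise scale sigma is the median absolute finest-level detail
    coefficient divided by 0.6745 (consistent for Gaussian noise).
    """
    sigma = np.median(np.abs(finest_detail)) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(max(n, 2))))


def _shrink(c: np.ndarray, thr: float, mode: str) -> np.ndarray:
    if mode == "soft":
        return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
    if mode == "hard":
        return np.where(np.abs(c) > thr, c, 0.0)
    raise ValueError(f"unknown threshold mode {mode!r}")


def denoise(x: np.ndarray, levels: int = 4, mode: str = "soft") -> np.ndarray:
    """Wavelet threshold denoising: decompose, shrink details, reconstruct.

    A single universal threshold, estimated from the finest detail level, is
    applied to every detail level; the approximation is left untouched. Output
    length equals input length.
    """
    x = np.asarray(x, dtype=float)
    approx, details, lengths = wavedec(x, levels)
    thr = universal_threshold(details[-1], x.size)
    details = [_shrink(d, thr, mode) for d in details]
    return waverec(approx, details, lengths)
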