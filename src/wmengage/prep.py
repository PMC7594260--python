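"""Nuisance regression, drift/bandpass filtering, standardization, fALFF.

The per-subject preprocessing order is fixed and logged:

    confound regression (motion-24 + CompCor)  ->  polynomial drift
    removal  ->  fALFF snapshot  ->  zero-phase bandpass  ->
    standardization to zero mean / unit variance.

fALFF is deliberately computed on the drift-corrected but *unfiltered*
series — after bandpassing the in-band fraction would be ~1 by
construction.

Functions accept either a plain (units x timepoints) array or a
:class:`~wmengage.types.TimeSeriesMatrix`; whichever comes in, a plain
array of the same shape comes out unless noted.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import TimeSeriesMatrix, values_of

__all__ = [
    "friston24_expand",
    "compcor_components",
    "regress_confounds",
    "detrend",
    "bandpass",
    "detrend_bandpass",
    "standardize",
    "compute_falff",
    "preprocess_subject",
]


def friston24_expand(motion6) -> np.ndarray:
    """Expand 6 rigid-body motion parameters to the 24-regressor model:
    [R(t), R(t-1), R(t)^2, R(t-1)^2], lagged rows zero-padded at t=0."""
    R = np.asarray(motion6, dtype=float)
    if R.ndim != 2 or R.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {R.shape}")
    if R.shape[0] < 2:
        raise ValueError("motion table needs at least 2 rows")
    R1 = np.vstack([np.zeros((1, 6)), R[:-1]])
    return np.hstack([R, R1, R ** 2, R1 ** 2])


def compcor_components(noise_roi_ts, k: int) -> np.ndarray:
    """Top-k principal component time courses of a noise-ROI signal set.

    Rows of ``noise_roi_ts`` are ROI voxels. Each voxel series is
    demeaned; the returned (timepoints x k) components are mutually
    orthogonal and scaled to unit variance. Requesting more components
    than the data's rank is an error.
    """
    X = np.atleast_2d(values_of(noise_roi_ts))
    if k <= 0:
        raise ValueError("k must be positive")
    nz = X.std(axis=1) > 0
    if int(nz.sum()) < k:
        raise ValueError(f"noise ROI has only {int(nz.sum())} voxels with variance, need >= {k}")
    X = X[nz] - X[nz].mean(axis=1, keepdims=True)
    # SVD over time: right singular vectors are the component time courses
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the ROI rank ({rank})")
    comp = Vt[:k].T
    comp = comp / comp.std(axis=0, ddof=1)
    return comp


def regress_confounds(ts, confounds) -> np.ndarray:
    """Least-squares residual of each row against [intercept, confounds].

    ``confounds`` is a (timepoints x p) design (no intercept column
    needed; one is always added). Collinear columns are dropped with a
    warning instead of failing.
    """
    Y = np.atleast_2d(values_of(ts))
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != Y.shape[1]:
        raise ValueError("confound rows must match the number of timepoints")
    X = np.hstack([np.ones((C.shape[0], 1)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy drop of columns that do not increase the rank
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        warnings.warn(
            f"rank-deficient confound design: dropped {X.shape[1] - len(keep)} collinear column(s)")
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def detrend(ts, order: int = 1) -> np.ndarray:
    """Remove a polynomial drift (default linear) from each row."""
    Y = np.atleast_2d(values_of(ts))
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    t = np.arange(Y.shape[1], dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)
    design = np.vander(t, order + 1, increasing=True)   # 1, t, t^2, ...
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    return Y - (design @ beta).T


def bandpass(ts, tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward filtering)."""
    Y = np.atleast_2d(values_of(ts))
    nyq = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, Nyquist={nyq:g}) Hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds,
                     output="sos")
    return sps.sosfiltfilt(sos, Y, axis=-1)


def detrend_bandpass(ts, tr_seconds: float = None, low_hz: float = 0.01,
                     high_hz: float = 0.1, drift_order: int = 1) -> np.ndarray:
    """Drift correction followed by the zero-phase bandpass."""
    if tr_seconds is None:
        if not isinstance(ts, TimeSeriesMatrix):
            raise ValueError("tr_seconds is required for plain arrays")
        tr_seconds = ts.tr_seconds
    return bandpass(detrend(ts, order=drift_order), tr_seconds, low_hz, high_hz)


def standardize(ts) -> np.ndarray:
    """Scale each row to zero mean and unit sample variance (n-1 divisor)."""
    Y = np.atleast_2d(values_of(ts))
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant series cannot be standardized (rows {bad[:10].tolist()})")
    return (Y - mu) / sd


def compute_falff(ts, tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.1):
    """Fractional amplitude of low-frequency fluctuations per row.

    Ratio of the power spectrum summed within the closed band
    [low_hz, high_hz] to the power summed over all positive frequencies
    (DC excluded), from the full-length unwindowed discrete Fourier
    transform. Input must be drift-corrected but not yet bandpassed,
    otherwise the ratio is ~1 by construction.
    """
    arr = values_of(ts)
    one_d = arr.ndim == 1
    Y = np.atleast_2d(arr)
    if Y.shape[1] < 64:
        raise ValueError("fALFF needs at least 64 timepoints")
    freqs = np.fft.rfftfreq(Y.shape[1], d=tr_seconds)
    amp = np.abs(np.fft.rfft(Y, axis=1)) ** 2
    pos = freqs > 0
    band = pos & (freqs >= low_hz) & (freqs <= high_hz)
    total = amp[:, pos].sum(axis=1)
    if np.any(total == 0):
        raise ValueError("series with zero total power")
    out = amp[:, band].sum(axis=1) / total
    return float(out[0]) if one_d else out


def preprocess_subject(series, tr_seconds: float, motion6=None, compcor_ts=None,
                       compcor_k: int = 5, low_hz: float = 0.01, high_hz: float = 0.1,
                       drift_order: int = 1):
    """Full per-subject preprocessing of a (units x timepoints) matrix.

    Returns ``(clean, falff, provenance)`` where ``clean`` is the
    confound-regressed, drift-corrected, bandpassed, standardized
    matrix, ``falff`` the per-row fALFF taken before filtering, and
    ``provenance`` a JSON-ready record of the stage order and
    parameters.
    """
    Y = np.atleast_2d(values_of(series))
    T = Y.shape[1]
    confounds = []
    prov_stages = []
    if motion6 is not None:
        confounds.append(friston24_expand(motion6))
        prov_stages.append({"stage": "motion_regression", "model": "friston24"})
    if compcor_ts is not None:
        confounds.append(compcor_components(compcor_ts, compcor_k))
        prov_stages.append({"stage": "compcor_regression", "k": compcor_k})
    if confounds:
        C = np.hstack(confounds)
        if C.shape[0] != T:
            raise ValueError("confound timepoints do not match the series")
        Y = regress_confounds(Y, C)
    Y = detrend(Y, order=drift_order)
    prov_stages.append({"stage": "drift_correction", "order": drift_order})
    falff = compute_falff(Y, tr_seconds, low_hz, high_hz)
    prov_stages.append({"stage": "falff_snapshot", "band_hz": [low_hz, high_hz]})
    Y = bandpass(Y, tr_seconds, low_hz, high_hz)
    prov_stages.append({"stage": "bandpass", "band_hz": [low_hz, high_hz],
                        "filter": "butterworth4_zero_phase"})
    Y = standardize(Y)
    prov_stages.append({"stage": "standardize", "ddof": 1})
    provenance = {"tr_seconds": tr_seconds, "stages": prov_stages}
    return Y, falff, provenance
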