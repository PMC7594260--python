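"""Per-voxel functional engagement of white matter in a GM node network.

For each WM voxel x the method compares the full Pearson correlation
matrix M of the GM node series with the first-order partial correlation
matrix M'_x in which x's control signal has been regressed out of every
node pair:

    r_ij.x = (r_ij - r_ix r_jx) / sqrt((1 - r_ix^2)(1 - r_jx^2))

The control signal is the average over the 5x5x5 WM-restricted cube
around x (boosting SNR), optionally advanced by a delay t in {0, 2, 4,
6} s to compensate for the slower WM hemodynamic response. Global
engagement of x is G(M) - G(M'_x), where G sums all pairwise
connectivities; local engagement with respect to node i is
L_i(M) - L_i(M'_x), where L_i averages node i's edges.

M is recomputed on each delay's truncated sample window so that M and
M'_x always come from identical samples.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .types import ConnectivityMatrix, EngagementMap, TimeSeriesMatrix, values_of

__all__ = [
    "extract_node_timeseries",
    "neighborhood_average",
    "neighborhood_average_all",
    "shift_control",
    "full_correlation",
    "partial_correlation",
    "partial_from_full",
    "global_metric",
    "local_metric",
    "local_metrics",
    "engagement_for_voxel",
    "engagement_map",
    "rescale_percent",
    "DEFAULT_DELAYS",
]

DEFAULT_DELAYS = (0.0, 2.0, 4.0, 6.0)
_COLLINEAR_TOL = 1e-10


def extract_node_timeseries(vol, node_labels, tr_seconds: float = None) -> TimeSeriesMatrix:
    """Mean time series per GM node label.

    ``vol`` is a 4D (x, y, z, t) array; ``node_labels`` a 3D integer
    volume (0 = background). Empty labels in the table are skipped (they
    simply have no voxels). Rows are ordered by ascending node id,
    recorded in ``unit_ids``.
    """
    vol = np.asarray(vol, dtype=float)
    labels = np.asarray(node_labels)
    if hasattr(node_labels, "values"):
        labels = np.asarray(node_labels.values)
    if vol.ndim != 4:
        raise ValueError("volume must be 4D (x, y, z, t)")
    if labels.shape != vol.shape[:3]:
        raise ValueError("node labels and volume are on mismatched grids")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no nonzero node labels")
    rows = np.empty((ids.size, vol.shape[3]))
    for r, i in enumerate(ids):
        rows[r] = vol[labels == i].mean(axis=0)
    return TimeSeriesMatrix(rows, tr_seconds=tr_seconds or 1.0, unit_ids=ids.astype(int))


def neighborhood_average(vol, wm_mask, voxel, size: int = 5) -> np.ndarray:
    """Control series for one WM voxel: mean over the size^3 axis-aligned
    cube centered at the voxel, intersected with the WM mask (center
    included, cube clipped at the grid edges)."""
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(wm_mask.values if hasattr(wm_mask, "values") else wm_mask, bool)
    if size % 2 != 1 or size < 1:
        raise ValueError("neighborhood size must be an odd positive integer")
    x, y, z = (int(c) for c in voxel)
    if not mask[x, y, z]:
        raise ValueError(f"voxel {voxel!r} is not inside the WM mask")
    h = size // 2
    sl = tuple(slice(max(c - h, 0), min(c + h + 1, s))
               for c, s in zip((x, y, z), mask.shape))
    sub_mask = mask[sl]
    return vol[sl][sub_mask].mean(axis=0)


def neighborhood_average_all(vol, wm_mask, size: int = 5):
    """Vectorized WM-restricted cube average for every mask voxel.

    Returns ``(controls, voxel_index)`` with ``controls`` of shape
    (V, T), rows matching the coordinate rows of ``voxel_index``. Agrees
    voxel-for-voxel with :func:`neighborhood_average`.
    """
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(wm_mask.values if hasattr(wm_mask, "values") else wm_mask, bool)
    if size % 2 != 1 or size < 1:
        raise ValueError("neighborhood size must be an odd positive integer")
    masked = vol * mask[..., None]
    # box-sum via a uniform filter; zero padding outside the grid matches
    # clipping the cube at the edges
    ksize = (size, size, size, 1)
    sums = ndimage.uniform_filter(masked, size=ksize, mode="constant", cval=0.0) * size ** 3
    counts = ndimage.uniform_filter(mask.astype(float), size=size,
                                    mode="constant", cval=0.0) * size ** 3
    counts = np.round(counts)
    voxel_index = np.argwhere(mask)
    ix = tuple(voxel_index.T)
    controls = sums[ix] / counts[ix][:, None]
    return controls, voxel_index


def shift_control(control, delay_seconds: float, tr_seconds: float):
    """Advance a control series to compensate a WM delay behind GM.

    The control sample at index n is replaced by the sample at n + lag
    (lag = delay / TR, which must be a whole number of samples; no
    sub-sample interpolation). Returns ``(advanced_control, window)``
    where ``window`` is the number of overlapping samples; the node
    series must be truncated to their first ``window`` samples.
    """
    control = np.asarray(control, dtype=float)
    T = control.shape[-1]
    lag = delay_to_lag(delay_seconds, tr_seconds)
    if lag >= T / 2:
        raise ValueError("delay removes more than half the samples")
    window = T - lag
    return control[..., lag:], window


def delay_to_lag(delay_seconds: float, tr_seconds: float) -> int:
    if delay_seconds < 0:
        raise ValueError("delay must be non-negative")
    lag = delay_seconds / tr_seconds
    if abs(lag - round(lag)) > 1e-9:
        raise ValueError(
            f"delay {delay_seconds} s is not a whole number of TRs (TR {tr_seconds} s)")
    return int(round(lag))


def _corr_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc ** 2).sum(axis=1))
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant series (rows {bad[:10].tolist()}) have no correlation")
    Z = Xc / sd[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def full_correlation(node_ts, delay_seconds: float = 0.0) -> ConnectivityMatrix:
    """Pearson correlation of every node pair (the full matrix M)."""
    X = np.atleast_2d(values_of(node_ts))
    return ConnectivityMatrix(_corr_rows(X), kind="full", delay_seconds=delay_seconds)


def partial_correlation(node_ts, control, delay_seconds: float = 0.0,
                        controlled_voxel=None) -> ConnectivityMatrix:
    """First-order partial correlation matrix M'_x controlling one series.

    Equivalent to correlating the residuals of every node series after
    regressing out the control. A control (near-)collinear with any node
    is rejected, naming the node.
    """
    X = np.atleast_2d(values_of(node_ts))
    c = np.asarray(values_of(control), dtype=float).ravel()
    if c.shape[0] != X.shape[1]:
        raise ValueError("control length must match the node series")
    R = _corr_rows(np.vstack([X, c]))
    a = R[:-1, -1]
    M = R[:-1, :-1]
    Mp = partial_from_full(M, a)
    return ConnectivityMatrix(Mp, kind="partial", delay_seconds=delay_seconds,
                              controlled_voxel=controlled_voxel)


def partial_from_full(M: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Closed-form first-order partial matrix from M and the node-control
    correlations a (a_i = r_ix)."""
    a = np.asarray(a, dtype=float)
    near = np.flatnonzero(np.abs(a) >= 1 - _COLLINEAR_TOL)
    if near.size:
        raise ValueError(
            f"control is collinear with node(s) {near.tolist()} (|r| >= 1 - 1e-10)")
    denom = np.sqrt(np.outer(1 - a ** 2, 1 - a ** 2))
    Mp = (M - np.outer(a, a)) / denom
    np.fill_diagonal(Mp, 1.0)
    return np.clip((Mp + Mp.T) / 2.0, -1.0, 1.0)


def global_metric(M) -> float:
    """G(M): signed sum of connectivities over unordered node pairs."""
    v = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, float)
    iu = np.triu_indices(v.shape[0], k=1)
    return float(v[iu].sum())


def local_metric(M, i: int, form: str = "mean") -> float:
    """L_i(M): connectivity of node i to all other nodes.

    ``form="mean"`` (default) averages over the n-1 edges at node i;
    ``form="sum"`` adds them, in which case sum_i L_i = 2 G(M).
    """
    v = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, float)
    n = v.shape[0]
    if not (0 <= i < n):
        raise IndexError(f"node index {i} out of range for {n} nodes")
    s = float(v[i].sum() - v[i, i])
    return s if form == "sum" else s / (n - 1)


def local_metrics(M, form: str = "mean") -> np.ndarray:
    """All L_i(M) at once."""
    v = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, float)
    s = v.sum(axis=1) - np.diag(v)
    return s if form == "sum" else s / (v.shape[0] - 1)


def engagement_for_voxel(node_ts, vol, wm_mask, voxel, delay_seconds: float,
                         tr_seconds: float = None, size: int = 5):
    """Global and local engagement of one WM voxel at one assumed delay.

    Composes: neighborhood average -> forward shift -> full and partial
    correlation on the same truncated window -> G and L differences.
    Returns ``(global_engagement, local_engagements)``; the local vector
    is in mean form, one entry per node row of ``node_ts``.
    """
    X = np.atleast_2d(values_of(node_ts))
    if tr_seconds is None:
        tr_seconds = node_ts.tr_seconds if isinstance(node_ts, TimeSeriesMatrix) else 1.0
    control = neighborhood_average(vol, wm_mask, voxel, size=size)
    control, window = shift_control(control, delay_seconds, tr_seconds)
    Xw = X[:, :window]
    M = full_correlation(Xw, delay_seconds=delay_seconds)
    Mp = partial_correlation(Xw, control, delay_seconds=delay_seconds,
                             controlled_voxel=tuple(int(c) for c in voxel))
    g = global_metric(M) - global_metric(Mp)
    l = local_metrics(M) - local_metrics(Mp)
    return g, l


def engagement_map(vol, node_ts, wm_mask, delays: Sequence[float] = DEFAULT_DELAYS,
                   tr_seconds: float = None, size: int = 5,
                   chunk: int = 256) -> Dict[float, EngagementMap]:
    """Engagement of every tight-mask WM voxel at each assumed delay.

    Vectorized over voxels; per-voxel failures (a control collinear with
    a node, or a constant control) are recorded in
    ``EngagementMap.failed_voxels`` and those voxels are dropped from
    the map rather than silently zeroed. Results are independent of the
    chunking.
    """
    X = np.atleast_2d(values_of(node_ts))
    if tr_seconds is None:
        tr_seconds = node_ts.tr_seconds if isinstance(node_ts, TimeSeriesMatrix) else 1.0
    node_ids = getattr(node_ts, "unit_ids", None)
    mask = np.asarray(wm_mask.values if hasattr(wm_mask, "values") else wm_mask, bool)
    controls, voxel_index = neighborhood_average_all(vol, wm_mask, size=size)
    n_nodes = X.shape[0]
    out: Dict[float, EngagementMap] = {}
    for delay in delays:
        ctrl_w, window = shift_control(controls, delay, tr_seconds)
        Xw = X[:, :window]
        M = _corr_rows(Xw)
        Lm = (M.sum(axis=1) - 1.0) / (n_nodes - 1)
        G = global_metric(M)
        Zn = Xw - Xw.mean(axis=1, keepdims=True)
        Zn /= np.sqrt((Zn ** 2).sum(axis=1, keepdims=True))

        V = ctrl_w.shape[0]
        g_vals = np.full(V, np.nan)
        l_vals = np.full((V, n_nodes), np.nan)
        ok = np.ones(V, dtype=bool)
        Cc = ctrl_w - ctrl_w.mean(axis=1, keepdims=True)
        c_sd = np.sqrt((Cc ** 2).sum(axis=1))
        const = c_sd == 0
        ok[const] = False
        iu = np.triu_indices(n_nodes, k=1)
        for start in range(0, V, chunk):
            sel = slice(start, min(start + chunk, V))
            rows = np.flatnonzero(ok[sel]) + start
            if rows.size == 0:
                continue
            A = (Cc[rows] / c_sd[rows][:, None]) @ Zn.T        # (v, n): r_ix
            A = np.clip(A, -1.0, 1.0)
            coll = np.abs(A).max(axis=1) >= 1 - _COLLINEAR_TOL
            if coll.any():
                ok[rows[coll]] = False
                rows = rows[~coll]
                A = A[~coll]
                if rows.size == 0:
                    continue
            f = np.sqrt(1.0 - A ** 2)                          # (v, n)
            Mp = (M[None, :, :] - A[:, :, None] * A[:, None, :]) \
                / (f[:, :, None] * f[:, None, :])
            Mp = np.clip(Mp, -1.0, 1.0)
            di = np.arange(n_nodes)
            Mp[:, di, di] = 1.0
            g_vals[rows] = G - Mp[:, iu[0], iu[1]].sum(axis=1)
            Lp = (Mp.sum(axis=2) - 1.0) / (n_nodes - 1)
            l_vals[rows] = Lm[None, :] - Lp
        failed = voxel_index[~ok]
        out[float(delay)] = EngagementMap(
            global_values=g_vals[ok],
            local_values=l_vals[ok],
            mask=mask,
            voxel_index=voxel_index[ok],
            delay_seconds=float(delay),
            rescaled=False,
            node_ids=None if node_ids is None else np.asarray(node_ids),
            failed_voxels=failed,
        )
    return out


def rescale_percent(emap: EngagementMap) -> EngagementMap:
    """Rescale a map to percent difference from its in-mask mean:
    e' = 100 (e - mean) / |mean|, which shifts the map mean to zero and
    removes inter-individual global scale differences."""
    if emap.rescaled:
        raise ValueError("map is already rescaled")
    mean = float(emap.global_values.mean())
    if abs(mean) < 1e-12:
        raise ValueError(
            f"map mean {mean:.3e} too close to zero for percent rescaling")
    g = 100.0 * (emap.global_values - mean) / abs(mean)
    l_out = np.empty_like(emap.local_values)
    for i in range(emap.local_values.shape[1]):
        col = emap.local_values[:, i]
        m = float(col.mean())
        if abs(m) < 1e-12:
            l_out[:, i] = np.nan
        else:
            l_out[:, i] = 100.0 * (col - m) / abs(m)
    return EngagementMap(
        global_values=g, local_values=l_out, mask=emap.mask,
        voxel_index=emap.voxel_index, delay_seconds=emap.delay_seconds,
        rescaled=True, node_ids=emap.node_ids, failed_voxels=emap.failed_voxels)
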