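"""Shared in-memory containers for the engagement pipeline.

The heavy lifting everywhere is done on plain numpy arrays; these
dataclasses carry the metadata (repetition time, grid, masks, flags)
that must travel with them between pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "EngagementMap",
    "values_of",
]


def values_of(ts) -> np.ndarray:
    """Return the underlying 2D array of a TimeSeriesMatrix or array-like."""
    if isinstance(ts, TimeSeriesMatrix):
        return ts.values
    return np.asarray(ts, dtype=float)


@dataclass
class TimeSeriesMatrix:
    """A units × timepoints real matrix (GM node means or voxel signals).

    Parameters
    ----------
    values : ndarray, shape (n_units, n_timepoints)
    tr_seconds : float
        Sampling interval (repetition time) of the series.
    standardized : bool
        True once every row has zero mean and unit (n-1) variance.
    band : (low_hz, high_hz) or None
        Passband applied to the series, if any.
    unit_ids : ndarray or None
        Optional identifiers for the rows (e.g. atlas node ids).
    """

    values: np.ndarray
    tr_seconds: float
    standardized: bool = False
    band: Optional[tuple] = None
    unit_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("TimeSeriesMatrix requires a 2D units x time array")
        if not np.isfinite(self.values).all():
            raise ValueError("TimeSeriesMatrix contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.standardized:
            m = self.values.mean(axis=1)
            v = self.values.var(axis=1, ddof=1)
            if np.abs(m).max(initial=0.0) > 1e-8 or np.abs(v - 1).max(initial=0.0) > 1e-6:
                raise ValueError("standardized flag set but rows are not standardized")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def with_values(self, values, **changes) -> "TimeSeriesMatrix":
        return replace(self, values=values, **changes)


@dataclass
class ConnectivityMatrix:
    """Symmetric node × node Pearson correlation matrix.

    ``kind`` is "full" for the plain correlation matrix M or "partial"
    for M'_x, the first-order partial correlation matrix in which one
    control (WM voxel) series has been regressed out of every pair.
    """

    values: np.ndarray
    kind: str = "full"
    controlled_voxel: Optional[tuple] = None
    delay_seconds: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("connectivity matrix must have a unit diagonal")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        if self.kind not in ("full", "partial"):
            raise ValueError("kind must be 'full' or 'partial'")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class EngagementMap:
    """Per-voxel engagement of WM voxels at one assumed hemodynamic delay.

    ``global_values[v]`` is G(M) - G(M'_x) for WM voxel v;
    ``local_values[v, i]`` is L_i(M) - L_i(M'_x) (mean form) for node i.
    Values are defined exactly on the voxels of ``mask`` (the tight
    population-based WM mask), listed in ``voxel_index`` order.
    """

    global_values: np.ndarray          # (V,)
    local_values: np.ndarray           # (V, n_nodes)
    mask: np.ndarray                   # 3D bool grid
    voxel_index: np.ndarray            # (V, 3) int coordinates
    delay_seconds: float
    rescaled: bool = False
    node_ids: Optional[np.ndarray] = None
    failed_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))

    def __post_init__(self):
        self.global_values = np.asarray(self.global_values, dtype=float)
        self.local_values = np.asarray(self.local_values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.global_values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("global_values and voxel_index length mismatch")
        if self.local_values.shape[0] != self.global_values.shape[0]:
            raise ValueError("local_values and global_values length mismatch")

    @property
    def n_voxels(self) -> int:
        return self.global_values.shape[0]

    def global_volume(self, fill=np.nan) -> np.ndarray:
        """Scatter the per-voxel global engagements back onto the 3D grid."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        ix = self.voxel_index
        vol[ix[:, 0], ix[:, 1], ix[:, 2]] = self.global_values
        return vol

    def value_at(self, voxel) -> float:
        """Global engagement at one (x, y, z) coordinate inside the mask."""
        voxel = tuple(int(c) for c in voxel)
        hit = np.flatnonzero((self.voxel_index == np.array(voxel)).all(axis=1))
        if hit.size == 0:
            raise KeyError(f"voxel {voxel} is not in the engagement map's mask")
        return float(self.global_values[hit[0]])
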