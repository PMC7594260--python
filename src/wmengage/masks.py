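"""Population-based tissue masks, GM node definitions and WM parcellations.

All thresholds are strict (">"): a voxel whose subject-averaged
probability equals the threshold exactly is excluded. Masks built from
the same probability maps are therefore nested: raising the threshold
can only remove voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "BinaryMask",
    "LabelVolume",
    "build_pb_mask",
    "define_gm_nodes",
    "split_wm_depth",
    "parcellate_tracts",
    "DEFAULT_DEEP_STRUCTURES",
]

# Default deep-WM structure names (JHU-DTI style). The deep/superficial
# split keys on atlas ids supplied at run time; this list documents which
# anatomical families the default deep set is meant to cover when a real
# tract atlas and its label table are provided.
DEFAULT_DEEP_STRUCTURES = (
    "genu of corpus callosum",
    "body of corpus callosum",
    "splenium of corpus callosum",
    "anterior corona radiata",
    "superior corona radiata",
    "posterior corona radiata",
    "anterior thalamic radiation",
    "posterior thalamic radiation",
    "sagittal stratum",
    "internal capsule",
    "external capsule",
    "superior longitudinal fasciculus",
    "inferior longitudinal fasciculus",
)


@dataclass
class BinaryMask:
    values: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D grid")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def __and__(self, other):
        return BinaryMask(self.values & np.asarray(other.values if isinstance(other, BinaryMask) else other, bool))


@dataclass
class LabelVolume:
    values: np.ndarray
    table: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("label volume must be a 3D grid")
        if not np.issubdtype(self.values.dtype, np.integer):
            v = np.asarray(self.values)
            if not np.allclose(v, np.round(v)):
                raise ValueError("label volume must be integer-valued")
            self.values = np.round(v).astype(np.int32)
        if self.values.min() < 0:
            raise ValueError("label volume must be non-negative (0 = background)")
        ids = self.ids
        if not self.table:
            self.table = {int(i): str(int(i)) for i in ids}
        missing = set(int(i) for i in ids) - set(int(k) for k in self.table)
        if missing:
            raise ValueError(f"label table is missing ids {sorted(missing)}")

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.values)
        return u[u > 0]


def _as_maps(prob_maps) -> np.ndarray:
    maps = [np.asarray(m, dtype=float) for m in prob_maps]
    if not maps:
        raise ValueError("need at least one probability map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("probability maps are on mismatched grids")
        if m.min() < -1e-9 or m.max() > 1 + 1e-9:
            raise ValueError("probability values must lie in [0, 1]")
    return np.stack(maps)


def build_pb_mask(prob_maps, threshold: float, label: str = "custom") -> BinaryMask:
    """Population-based mask: voxels whose mean probability across
    subjects strictly exceeds ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    stack = _as_maps(prob_maps)
    return BinaryMask(stack.mean(axis=0) > threshold, label=label)


def define_gm_nodes(gm_mask: BinaryMask, atlas: LabelVolume) -> LabelVolume:
    """Restrict an atlas of GM nodes to the population GM mask.

    Nodes left with zero voxels are dropped from the output table and
    reported with a warning; if every node empties out, that is an error.
    """
    mask = gm_mask.values if isinstance(gm_mask, BinaryMask) else np.asarray(gm_mask, bool)
    if mask.shape != atlas.values.shape:
        raise ValueError("mask and atlas are on mismatched grids")
    out = np.where(mask, atlas.values, 0)
    kept = set(int(i) for i in np.unique(out) if i > 0)
    if not kept:
        raise ValueError("no nodes: the GM mask removes every atlas label")
    empty = [i for i in atlas.table if i not in kept]
    if empty:
        warnings.warn(f"nodes emptied by the GM mask: {sorted(empty)}")
    table = {i: n for i, n in atlas.table.items() if i in kept}
    return LabelVolume(out.astype(np.int32), table)


def split_wm_depth(wm_prob_maps, deep_atlas: LabelVolume, deep_ids: Iterable[int],
                   loose_threshold: float = 0.5):
    """Partition the loose WM mask into superficial and deep components.

    The loose mask (mean probability > ``loose_threshold``, default 0.5,
    chosen to retain sub-cortical WM) is split by overlap with the
    supplied deep tract structures: deep = loose ∩ (atlas id in
    ``deep_ids``), superficial = the remainder. The partition is exact.
    """
    deep_ids = set(int(i) for i in deep_ids)
    if not deep_ids:
        raise ValueError("deep_ids must be non-empty")
    extra = deep_ids - set(int(i) for i in deep_atlas.ids)
    if extra:
        raise ValueError(f"deep_ids not present in the atlas: {sorted(extra)}")
    loose = build_pb_mask(wm_prob_maps, loose_threshold, label="PB_WM_loose")
    if loose.values.shape != deep_atlas.values.shape:
        raise ValueError("probability maps and deep atlas are on mismatched grids")
    in_deep = np.isin(deep_atlas.values, sorted(deep_ids))
    deep = BinaryMask(loose.values & in_deep, label="deep")
    superficial = BinaryMask(loose.values & ~in_deep, label="superficial")
    return superficial, deep


def parcellate_tracts(wm_mask: BinaryMask, tract_atlas: LabelVolume,
                      keep_ids: Optional[Iterable[int]] = None) -> LabelVolume:
    """Restrict a tract atlas to the WM mask, keeping only ``keep_ids``.

    Tracts that end up with zero voxels inside the mask are dropped from
    the table and reported via warning (small structures near cortex
    routinely vanish under a tight WM threshold).
    """
    mask = wm_mask.values if isinstance(wm_mask, BinaryMask) else np.asarray(wm_mask, bool)
    if mask.shape != tract_atlas.values.shape:
        raise ValueError("mask and tract atlas are on mismatched grids")
    if keep_ids is None:
        keep_ids = set(int(i) for i in tract_atlas.ids)
    else:
        keep_ids = set(int(i) for i in keep_ids)
    keep_vol = np.isin(tract_atlas.values, sorted(keep_ids))
    out = np.where(mask & keep_vol, tract_atlas.values, 0)
    present = set(int(i) for i in np.unique(out) if i > 0)
    empty = sorted(i for i in keep_ids if i not in present and i in tract_atlas.table)
    if empty:
        warnings.warn(f"tracts not covered by the WM mask: {empty}")
    table = {i: n for i, n in tract_atlas.table.items() if i in present}
    return LabelVolume(out.astype(np.int32), table)
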