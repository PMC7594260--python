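"""Tract-level and depth-level summaries of engagement results."""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .masks import BinaryMask, LabelVolume
from .types import EngagementMap

__all__ = [
    "tract_counts",
    "falff_by_tract",
    "engagement_falff_correlation",
    "depth_comparison",
]


def _mask_values(mask) -> np.ndarray:
    return np.asarray(mask.values if hasattr(mask, "values") else mask, bool)


def tract_counts(sig_mask, tracts: LabelVolume) -> pd.DataFrame:
    """Significant-voxel count per tract: |sig_mask ∩ tract| for every
    tract id, alongside the tract's total voxel count."""
    sig = _mask_values(sig_mask)
    lab = tracts.values
    if sig.shape != lab.shape:
        raise ValueError("significance mask and tract atlas are on mismatched grids")
    rows = []
    for i, name in sorted(tracts.table.items()):
        in_tract = lab == i
        rows.append({
            "tract_id": int(i),
            "tract_name": name,
            "n_voxels": int(in_tract.sum()),
            "n_significant": int((sig & in_tract).sum()),
        })
    return pd.DataFrame(rows)


def falff_by_tract(falff_maps: Sequence[np.ndarray], tracts: LabelVolume) -> pd.DataFrame:
    """Population fALFF per tract: each subject's fALFF volume is
    averaged over the tract's voxels, then mean ± SD is taken across
    subjects."""
    lab = tracts.values
    per_subj = {i: [] for i in tracts.table}
    for vol in falff_maps:
        vol = np.asarray(vol, dtype=float)
        if vol.shape != lab.shape:
            raise ValueError("fALFF map grid does not match the tract atlas")
        for i in per_subj:
            vals = vol[lab == i]
            per_subj[i].append(float(np.nanmean(vals)) if vals.size else np.nan)
    rows = []
    for i, name in sorted(tracts.table.items()):
        v = np.asarray(per_subj[i], dtype=float)
        rows.append({
            "tract_id": int(i),
            "tract_name": name,
            "falff_mean": float(np.nanmean(v)),
            "falff_sd": float(np.nanstd(v, ddof=1)) if v.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def engagement_falff_correlation(counts, falff):
    """Pearson correlation between per-tract significant-voxel counts and
    per-tract mean fALFF.

    ``counts`` and ``falff`` are equal-length vectors over tracts (pass
    the relevant columns of :func:`tract_counts` /
    :func:`falff_by_tract` output). Returns ``(r, p, n)``.
    """
    x = np.asarray(counts, dtype=float)
    y = np.asarray(falff, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("counts and fALFF must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 tracts with defined values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def depth_comparison(maps_by_delay: Mapping[float, Sequence[EngagementMap]],
                     superficial: BinaryMask, deep: BinaryMask,
                     test: str = "t") -> pd.DataFrame:
    """Superficial-vs-deep engagement across subjects, per delay.

    For each subject and delay the rescaled engagement map is averaged
    within the superficial and the deep mask; the two depth series are
    compared with a paired two-sided t-test (or Wilcoxon signed-rank
    with ``test="wilcoxon"``). A constant nonzero paired difference has
    no sample variance; it is reported with p at the machine floor.

    Returns one row per delay with the per-depth group means, the test
    statistic and p-value; per-subject means are in the ``subject_*``
    columns as lists.
    """
    sup = _mask_values(superficial)
    dp = _mask_values(deep)
    if (sup & dp).any():
        raise ValueError("superficial and deep masks must be disjoint")
    rows = []
    for delay, maps in sorted(maps_by_delay.items()):
        sup_means, deep_means = [], []
        for m in maps:
            if not m.rescaled:
                raise ValueError("depth comparison expects rescaled maps")
            vol = m.global_volume()
            s_vals = vol[sup]
            d_vals = vol[dp]
            s_vals = s_vals[np.isfinite(s_vals)]
            d_vals = d_vals[np.isfinite(d_vals)]
            if s_vals.size == 0 or d_vals.size == 0:
                raise ValueError("a depth mask has no voxels inside the engagement map")
            sup_means.append(float(s_vals.mean()))
            deep_means.append(float(d_vals.mean()))
        sup_arr, deep_arr = np.asarray(sup_means), np.asarray(deep_means)
        diff = sup_arr - deep_arr
        if np.ptp(diff) == 0:
            if diff[0] == 0:
                stat, p = 0.0, 1.0
            else:   # exact constant difference: no variance, p at the floor
                stat = np.inf * np.sign(diff[0])
                p = np.finfo(float).tiny
        elif test == "t":
            stat, p = stats.ttest_rel(sup_arr, deep_arr)
        elif test == "wilcoxon":
            stat, p = stats.wilcoxon(sup_arr, deep_arr)
        else:
            raise ValueError("test must be 't' or 'wilcoxon'")
        rows.append({
            "delay_seconds": float(delay),
            "superficial_mean": float(sup_arr.mean()),
            "deep_mean": float(deep_arr.mean()),
            "statistic": float(stat),
            "p_value": float(p),
            "n_subjects": len(maps),
            "subject_superficial": sup_means,
            "subject_deep": deep_means,
        })
    return pd.DataFrame(rows)
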