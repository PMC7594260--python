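"""Group-level inference on engagement maps.

Voxel-wise one-sample t-tests against zero across subjects,
Benjamini-Hochberg FDR thresholding within the analysis (tight WM)
mask, and split-half reproducibility of the group-mean map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .masks import BinaryMask
from .types import EngagementMap

__all__ = [
    "GroupStatMap",
    "stack_maps",
    "one_sample_ttest",
    "fdr_bh",
    "split_half_reproducibility",
    "split_half_null_band",
]


@dataclass
class GroupStatMap:
    """Voxel-wise group statistics over one delay's engagement maps."""

    t_values: np.ndarray          # (V,)
    p_values: np.ndarray          # (V,), two-sided
    voxel_index: np.ndarray       # (V, 3)
    mask: np.ndarray              # 3D analysis mask
    n_subjects: int
    delay_seconds: float
    q_threshold: Optional[float] = None
    significant: Optional[np.ndarray] = None     # (V,) bool after FDR
    zero_variance: Optional[np.ndarray] = None   # (V,) bool, excluded from FDR

    @property
    def df(self) -> int:
        return self.n_subjects - 1

    def significance_mask(self) -> BinaryMask:
        if self.significant is None:
            raise ValueError("run fdr first (q_threshold unset)")
        vol = np.zeros(self.mask.shape, dtype=bool)
        ix = self.voxel_index[self.significant]
        vol[ix[:, 0], ix[:, 1], ix[:, 2]] = True
        return BinaryMask(vol, label="significant")

    def volume(self, which: str = "t", fill=np.nan) -> np.ndarray:
        vals = {"t": self.t_values, "p": self.p_values}[which]
        vol = np.full(self.mask.shape, fill, dtype=float)
        ix = self.voxel_index
        vol[ix[:, 0], ix[:, 1], ix[:, 2]] = vals
        return vol


def stack_maps(maps: Sequence[EngagementMap]) -> np.ndarray:
    """Stack subject maps into (n_subjects, V), checking aligned voxels."""
    if len(maps) == 0:
        raise ValueError("no maps")
    first = maps[0]
    for m in maps[1:]:
        if m.voxel_index.shape != first.voxel_index.shape or \
                not np.array_equal(m.voxel_index, first.voxel_index):
            raise ValueError("subject maps cover different voxel sets")
    return np.vstack([m.global_values for m in maps])


def one_sample_ttest(maps: Sequence[EngagementMap], q: float = None) -> GroupStatMap:
    """Voxel-wise one-sample t-test of the subject maps against zero.

    Two-sided p from the t distribution with n-1 degrees of freedom.
    Voxels with zero cross-subject variance have no defined t; they are
    flagged and excluded from any subsequent FDR step. If ``q`` is
    given, BH-FDR thresholding is applied immediately.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects for a group t-test")
    if not all(m.rescaled for m in maps):
        raise ValueError("group test expects rescaled (percent) maps")
    data = stack_maps(maps)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = sd == 0
    t = np.full(mean.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[~zero_var] = mean[~zero_var] / (sd[~zero_var] / np.sqrt(n))
    p = np.full(mean.shape, np.nan)
    p[~zero_var] = 2.0 * stats.t.sf(np.abs(t[~zero_var]), df=n - 1)
    out = GroupStatMap(t_values=t, p_values=p, voxel_index=maps[0].voxel_index,
                       mask=maps[0].mask, n_subjects=n,
                       delay_seconds=maps[0].delay_seconds,
                       zero_variance=zero_var)
    if q is not None:
        sig = fdr_bh(p[~zero_var], q)
        full_sig = np.zeros(mean.shape, dtype=bool)
        full_sig[~zero_var] = sig
        out.q_threshold = q
        out.significant = full_sig
    return out


def fdr_bh(p_values, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the k smallest p-values where
    k = max{i : p_(i) <= i q / m}. Returns a boolean rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1] with no NaNs")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def split_half_reproducibility(maps: Sequence[EngagementMap], seed: int):
    """Seeded random split into halves; Pearson r between the two
    half-sample mean maps, with a Fisher-z 95% CI.

    Returns ``(mean_a, mean_b, r, (ci_low, ci_high), split)`` where
    ``split`` records the subject indices of each half.
    """
    if len(maps) < 4:
        raise ValueError("need at least 4 subjects for a split-half analysis")
    data = stack_maps(maps)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    a_idx, b_idx = np.sort(perm[:half]), np.sort(perm[half:])
    mean_a = data[a_idx].mean(axis=0)
    mean_b = data[b_idx].mean(axis=0)
    if mean_a.std() == 0 or mean_b.std() == 0:
        raise ValueError("degenerate (constant) half-sample mean map")
    r = float(np.corrcoef(mean_a, mean_b)[0, 1])
    V = mean_a.size
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / np.sqrt(V - 3)
    ci = (float(np.tanh(z - 1.959963984540054 * zse)),
          float(np.tanh(z + 1.959963984540054 * zse)))
    return mean_a, mean_b, r, ci, {"group_a": a_idx.tolist(), "group_b": b_idx.tolist()}


def split_half_null_band(maps: Sequence[EngagementMap], seed: int,
                         n_permutations: int = 200, alpha: float = 0.01) -> float:
    """Monte-Carlo null band for the split-half correlation.

    Repeatedly re-splits the cohort at random and flips each subject
    map's sign at random (breaking any structure shared across
    subjects), then records |r| between half-mean maps. Returns the
    (1 - alpha) quantile of |r| — the magnitude a genuinely shared
    spatial pattern must exceed.
    """
    data = stack_maps(maps)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    half = n // 2
    rs = np.empty(n_permutations)
    for i in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None]
        flipped = data * signs
        perm = rng.permutation(n)
        a = flipped[perm[:half]].mean(axis=0)
        b = flipped[perm[half:]].mean(axis=0)
        rs[i] = abs(np.corrcoef(a, b)[0, 1])
    return float(np.quantile(rs, 1 - alpha))
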