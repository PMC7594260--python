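"""Reusable synthetic-study harnesses.

Each function here runs the *real* pipeline end-to-end on a generated
cohort — masks from the probabilistic maps, per-voxel preprocessing,
neighborhood-averaged delayed controls, partial-correlation engagement,
percent rescaling, group statistics — and reports a recovery or
calibration quantity. They are the package's own validation
experiments: mediator recovery, lag recovery, null calibration,
split-half reproducibility, FDR calibration.

Study conditions
----------------
The recovery studies use a 14x14x14 phantom whose interior WM core has
10^3 = 1000 voxels: large enough for a top-1% rank to mean something
(top 10 voxels) while staying desk-scale. Mediators are planted as
3x3x3 clusters (see :func:`wmengage.simulate.mediator_cluster`): the
5x5x5 neighborhood-averaged control mandated by the method dilutes an
isolated single-voxel signal ~125-fold and makes it indistinguishable
from its neighbors, whereas real WM BOLD fluctuations — and hence
recoverable ones — extend over contiguous voxels. Ranks and lags are
evaluated at the cluster's center voxel.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from . import engagement as eng
from . import group as grp
from . import prep
from .masks import LabelVolume, build_pb_mask, define_gm_nodes
from .simulate import (Cohort, SimulationConfig, generate_cohort,
                       mediator_cluster, truth_engagement_ranks)
from .types import EngagementMap

__all__ = [
    "recovery_config",
    "run_cohort_pipeline",
    "mean_map",
    "engagement_of_controls",
    "null_engagement_band",
    "mediator_recovery_trial",
    "lag_recovery_trial",
    "null_calibration_study",
    "split_half_study",
    "fdr_calibration",
]

RECOVERY_GRID = (14, 14, 14)
CLUSTER_CENTER = (7, 7, 7)
DRIVEN_NODES = (1, 2, 3)


def recovery_config(seed: int, lag_samples: int = 0, weight: float = 0.9,
                    n_subjects: int = 10, n_timepoints: int = 200,
                    noise_ar1: float = 0.3, noise_sd: float = 0.5,
                    center=CLUSTER_CENTER, cluster_radius: int = 1,
                    extra_clusters=()) -> SimulationConfig:
    """Standard mediator-recovery study conditions."""
    mediators = list(mediator_cluster(center, lag_samples, weight, DRIVEN_NODES,
                                      radius=cluster_radius))
    for (c, lag, w) in extra_clusters:
        mediators += mediator_cluster(c, lag, w, DRIVEN_NODES, radius=cluster_radius)
    return SimulationConfig(
        grid_shape=RECOVERY_GRID, n_timepoints=n_timepoints, tr_seconds=2.0,
        n_nodes=5, n_subjects=n_subjects, mediators=mediators,
        noise_ar1=noise_ar1, noise_sd=noise_sd, seed=seed)


def run_cohort_pipeline(cohort: Cohort, delays: Sequence[float] = (0.0,),
                        compcor_k: int = 5, size: int = 5,
                        rescale: bool = True) -> dict:
    """Masks -> preprocessing -> engagement for every subject.

    Returns a dict with the masks, per-subject preprocessed node series,
    raw and (optionally) rescaled engagement maps keyed by delay, and
    per-subject fALFF volumes.
    """
    cfg = cohort.config
    wm_tight = build_pb_mask(cohort.wm_prob, 0.95, label="PB_WM_tight")
    gm_mask = build_pb_mask(cohort.gm_prob, 0.6, label="PB_GM")
    nodes = define_gm_nodes(gm_mask, LabelVolume(cohort.node_labels, cohort.node_table))

    raw: Dict[float, list] = {float(d): [] for d in delays}
    rescaled: Dict[float, list] = {float(d): [] for d in delays}
    node_ts_list, falff_vols = [], []
    for s in range(cohort.n_subjects):
        vol = cohort.bold[s]
        tissue = (cohort.gm_prob[s] > 0) | (cohort.wm_prob[s] > 0) | (cohort.csf_prob[s] > 0)
        csf = cohort.csf_prob[s] > 0.95
        series = vol[tissue]
        clean, falff, _ = prep.preprocess_subject(
            series, cfg.tr_seconds, motion6=cohort.motion[s],
            compcor_ts=vol[csf], compcor_k=compcor_k)
        clean_vol = np.zeros_like(vol)
        clean_vol[tissue] = clean
        fvol = np.full(cfg.grid_shape, np.nan)
        fvol[tissue] = falff
        falff_vols.append(fvol)

        node_ts = eng.extract_node_timeseries(clean_vol, nodes.values,
                                              tr_seconds=cfg.tr_seconds)
        node_ts_list.append(node_ts)
        maps = eng.engagement_map(clean_vol, node_ts, wm_tight, delays=delays,
                                  tr_seconds=cfg.tr_seconds, size=size)
        for d, m in maps.items():
            raw[d].append(m)
            if rescale:
                rescaled[d].append(eng.rescale_percent(m))
    return {
        "wm_tight": wm_tight, "gm_mask": gm_mask, "nodes": nodes,
        "node_ts": node_ts_list, "falff": falff_vols,
        "raw_maps": raw, "rescaled_maps": rescaled if rescale else None,
    }


def mean_map(maps: Sequence[EngagementMap]) -> EngagementMap:
    """Voxel-wise group mean of aligned subject maps."""
    data = grp.stack_maps(maps)
    first = maps[0]
    return EngagementMap(
        global_values=data.mean(axis=0),
        local_values=np.mean([m.local_values for m in maps], axis=0),
        mask=first.mask, voxel_index=first.voxel_index,
        delay_seconds=first.delay_seconds, rescaled=first.rescaled,
        node_ids=first.node_ids)


def engagement_of_controls(node_ts, controls) -> np.ndarray:
    """Global engagement produced by each row of ``controls`` (K, T)."""
    X = np.atleast_2d(np.asarray(node_ts.values if hasattr(node_ts, "values") else node_ts,
                                 dtype=float))
    C = np.atleast_2d(np.asarray(controls, dtype=float))
    M = eng.full_correlation(X).values
    G = eng.global_metric(M)
    out = np.empty(C.shape[0])
    Zn = X - X.mean(axis=1, keepdims=True)
    Zn /= np.sqrt((Zn ** 2).sum(axis=1, keepdims=True))
    for k in range(C.shape[0]):
        c = C[k] - C[k].mean()
        c /= np.sqrt((c ** 2).sum())
        a = np.clip(Zn @ c, -1, 1)
        out[k] = G - eng.global_metric(eng.partial_from_full(M, a))
    return out


def null_engagement_band(node_ts_list, tr_seconds: float, seed: int,
                         n_controls: int = 200, noise_ar1: float = 0.3,
                         alpha: float = 0.01) -> float:
    """Monte-Carlo r-null band for *group-mean* global engagement.

    Draws AR(1) controls that are independent of every node by
    construction, pushes them through the same drift/bandpass/
    standardize chain as real controls, computes each control's
    engagement per subject, averages across subjects, and returns the
    (1 - alpha) quantile of the absolute group-mean engagement.
    """
    rng = np.random.default_rng(seed)
    T = node_ts_list[0].n_timepoints
    samples = np.zeros((len(node_ts_list), n_controls))
    from scipy.signal import lfilter
    for s, node_ts in enumerate(node_ts_list):
        white = rng.standard_normal((n_controls, T))
        ctrl = lfilter([1.0], [1.0, -noise_ar1], white, axis=-1) if noise_ar1 else white
        ctrl = prep.standardize(prep.bandpass(prep.detrend(ctrl), tr_seconds))
        samples[s] = engagement_of_controls(node_ts, ctrl)
    group_mean = samples.mean(axis=0)
    return float(np.quantile(np.abs(group_mean), 1 - alpha))


def mediator_recovery_trial(seed: int, q: float = 0.01) -> dict:
    """One repetition of the mediator-recovery experiment.

    Plants a weight-0.9, lag-0 mediator cluster and runs the pipeline
    at 0 s delay. Reports, on the group-mean map: whether every voxel
    in the top 1% is a planted mediator (the cluster should own the top
    of the ranking), the cluster center's percentile against the
    non-mediator (null) voxels, and whether the center is
    FDR-significant at ``q``. Recovery = top-1% purity + significance.
    """
    cfg = recovery_config(seed, lag_samples=0, weight=0.9)
    cohort = generate_cohort(cfg)
    res = run_cohort_pipeline(cohort, delays=(0.0,))
    rescaled = res["rescaled_maps"][0.0]
    gmap = mean_map(rescaled)
    ranks = truth_engagement_ranks(cohort.truth, gmap, against="non_mediator")
    center_row = ranks[ranks["voxel"] == CLUSTER_CENTER].iloc[0]
    # are the top-1% most engaged voxels all planted mediators?
    v = gmap.global_values
    n_top = max(int(np.ceil(0.01 * v.size)), 1)
    top_idx = np.argsort(v)[::-1][:n_top]
    med_set = {tuple(x) for x in cohort.truth.mediator_voxels}
    top_all_planted = all(tuple(gmap.voxel_index[i]) in med_set for i in top_idx)
    stat = grp.one_sample_ttest(rescaled, q=q)
    sig_vol = stat.significance_mask().values
    significant = bool(sig_vol[CLUSTER_CENTER])
    return {
        "rank_percentile": float(center_row["percentile"]),
        "top1pct_all_planted": bool(top_all_planted),
        "significant": significant,
        "recovered": bool(top_all_planted and significant),
        "n_wm_voxels": int(res["wm_tight"].n_voxels),
    }


def lag_recovery_trial(seed: int, lag_samples: int = 2,
                       delays: Sequence[float] = (0.0, 2.0, 4.0, 6.0)) -> dict:
    """One repetition of the lag-recovery experiment.

    Plants the mediator cluster at ``lag_samples`` (2 samples = 4 s at
    TR 2 s) and reports which assumed delay maximizes the cluster
    center's group-mean raw engagement.
    """
    cfg = recovery_config(seed, lag_samples=lag_samples, weight=0.9)
    cohort = generate_cohort(cfg)
    res = run_cohort_pipeline(cohort, delays=delays, rescale=False)
    by_delay = {}
    for d in delays:
        gmap = mean_map(res["raw_maps"][float(d)])
        by_delay[float(d)] = gmap.value_at(CLUSTER_CENTER)
    best = max(by_delay, key=by_delay.get)
    return {"engagement_by_delay": by_delay, "argmax_delay_seconds": best,
            "planted_delay_seconds": lag_samples * cfg.tr_seconds}


def null_calibration_study(seed: int, n_subjects: int = 10, q: float = 0.01,
                           grid=(10, 10, 10), n_controls: int = 200) -> dict:
    """Null cohort (zero mediators): FDR calibration and raw-engagement
    magnitudes against the Monte-Carlo r-null band.

    The effective number of independent WM units is taken conservatively
    as the number of disjoint 5^3 neighborhoods, since adjacent voxels
    share almost their entire control cube.
    """
    cfg = SimulationConfig(grid_shape=grid, n_timepoints=200, tr_seconds=2.0,
                           n_nodes=5, n_subjects=n_subjects, seed=seed)
    cohort = generate_cohort(cfg)
    res = run_cohort_pipeline(cohort, delays=(0.0,))
    rescaled = res["rescaled_maps"][0.0]
    raw = res["raw_maps"][0.0]

    stat = grp.one_sample_ttest(rescaled, q=q)
    n_vox = stat.t_values.size
    frac_sig = float(stat.significant.sum()) / n_vox

    raw_stack = grp.stack_maps(raw)
    spatial_means = raw_stack.mean(axis=1)
    from scipy import stats as sstats
    t_mean, p_mean = sstats.ttest_1samp(spatial_means, 0.0)

    band = null_engagement_band(res["node_ts"], cfg.tr_seconds, seed=seed + 1,
                                n_controls=n_controls, noise_ar1=cfg.noise_ar1)
    group_raw = raw_stack.mean(axis=0)
    frac_beyond = float(np.mean(np.abs(group_raw) > band))
    n_eff = max(n_vox // 125, 1)
    return {
        "q": q, "n_voxels": n_vox, "frac_fdr_significant": frac_sig,
        "fdr_bound": q + 2 * np.sqrt(q * (1 - q) / n_vox),
        "spatial_mean_t": float(t_mean), "spatial_mean_p": float(p_mean),
        "null_band_99": band, "frac_beyond_band": frac_beyond,
        "beyond_band_bound": 0.01 + 2 * np.sqrt(0.01 * 0.99 / n_eff),
    }


def split_half_study(seed: int, with_mediators: bool, n_subjects: int = 20,
                     weight: float = 0.8) -> dict:
    """Split-half reproducibility of the group map at 0 s delay.

    With mediators: two weight-``weight`` lag-0 clusters shared by all
    subjects; the half-map correlation should be high. Without: pure
    noise; |r| should sit inside the permutation null band.
    """
    if with_mediators:
        cfg = recovery_config(seed, lag_samples=0, weight=weight,
                              n_subjects=n_subjects, center=(4, 4, 4),
                              extra_clusters=(((9, 9, 9), 0, weight),))
    else:
        cfg = SimulationConfig(grid_shape=RECOVERY_GRID, n_timepoints=200,
                               tr_seconds=2.0, n_nodes=5, n_subjects=n_subjects,
                               seed=seed)
    cohort = generate_cohort(cfg)
    res = run_cohort_pipeline(cohort, delays=(0.0,))
    maps = res["rescaled_maps"][0.0]
    _, _, r, ci, split = grp.split_half_reproducibility(maps, seed=seed + 1)
    band = grp.split_half_null_band(maps, seed=seed + 2, n_permutations=200)
    return {"r": r, "ci": ci, "null_band_99": band, "split": split}


def fdr_calibration(q: float, seed: int, n_reps: int = 500, m_null: int = 900,
                    m_signal: int = 100) -> dict:
    """Empirical false-discovery proportion of BH over mixed p-values.

    Null p-values are Uniform(0, 1); signal p-values are ~0 (1e-8 scale).
    Returns the mean FDP over ``n_reps`` repetitions and its Monte-Carlo
    standard error.
    """
    rng = np.random.default_rng(seed)
    fdps = np.empty(n_reps)
    for i in range(n_reps):
        p = np.concatenate([rng.uniform(size=m_null),
                            1e-8 * rng.uniform(size=m_signal)])
        is_null = np.zeros(p.size, dtype=bool)
        is_null[:m_null] = True
        reject = grp.fdr_bh(p, q)
        n_rej = int(reject.sum())
        fdps[i] = (reject & is_null).sum() / n_rej if n_rej else 0.0
    return {"q": q, "mean_fdp": float(fdps.mean()),
            "mc_se": float(fdps.std(ddof=1) / np.sqrt(n_reps)),
            "n_reps": n_reps}
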