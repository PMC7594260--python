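"""Synthetic resting-state cohorts with planted white-matter mediators.

The generator builds everything the downstream pipeline consumes — 4D
BOLD volumes, probabilistic GM/WM/CSF maps, node and tract label
volumes, 6-column motion tables — on a small cuboid phantom, with a
known latent network among the GM nodes and, optionally, WM voxels
("mediators") that carry a delayed, weighted copy of the latent signal
shared by a chosen node set. Those mediators are the ground truth that
the engagement computation is expected to recover.

Geometry
--------
GM nodes are disjoint strips on the z = 0 face of the grid; CSF is the
opposite face (z = nz-1); WM is an interior cuboid core with a 1-voxel
shell of intermediate (0.7) WM probability around it, so that the
0.95 / 0.6 / 0.5 mask thresholds all bite. The WM core is split into
slabs along z to provide a toy tract atlas.

Signal model
------------
Per subject, an n_nodes-variate latent series is drawn i.i.d. over time
from ``node_covariance``. Every GM voxel of node i carries that node's
latent series plus white voxel noise. A mediator at lag k carries
``weight * mean(latent of its driven nodes)`` reproduced k samples
LATER than in GM, plus AR(1) noise; all other WM (and CSF) voxels carry
pure AR(1) noise. The forward shift applied by the engagement core is
exactly the operation that undoes lag k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import nibabel as nib

__all__ = [
    "MediatorSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "Cohort",
    "default_node_covariance",
    "mediator_cluster",
    "generate_cohort",
    "truth_engagement_ranks",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class MediatorSpec:
    """One planted WM mediator voxel.

    voxel : (x, y, z) grid coordinate (must lie in the WM core)
    lag_samples : the mediator reproduces the latent signal this many
        samples later than GM (>= 0)
    weight : mixing weight of the latent signal, in (0, 1]
    driven_nodes : node ids (1-based atlas labels) whose latent mean
        the mediator carries
    """

    voxel: tuple
    lag_samples: int
    weight: float
    driven_nodes: tuple

    def __post_init__(self):
        object.__setattr__(self, "voxel", tuple(int(c) for c in self.voxel))
        object.__setattr__(self, "driven_nodes", tuple(int(i) for i in self.driven_nodes))
        if self.lag_samples < 0:
            raise ValueError("lag_samples must be >= 0")
        if not (0 < self.weight <= 1):
            raise ValueError("weight must be in (0, 1]")
        if not self.driven_nodes:
            raise ValueError("driven_nodes must be non-empty")


@dataclass
class SimulationConfig:
    grid_shape: tuple = (8, 8, 8)
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    n_nodes: int = 5
    n_subjects: int = 10
    node_covariance: Optional[np.ndarray] = None
    mediators: Sequence[MediatorSpec] = field(default_factory=tuple)
    noise_ar1: float = 0.3
    noise_sd: float = 0.5
    gm_voxel_noise_sd: float = 0.5
    motion_step_sd: float = 0.02
    n_tracts: int = 3
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 6:
            raise ValueError("grid_shape must be 3 axes of at least 6 voxels")
        if self.n_timepoints <= 0 or self.n_nodes <= 0 or self.n_subjects <= 0:
            raise ValueError("n_timepoints, n_nodes, n_subjects must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not (0 <= self.noise_ar1 < 1):
            raise ValueError("noise_ar1 must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.node_covariance is None:
            self.node_covariance = default_node_covariance(self.n_nodes)
        self.node_covariance = np.asarray(self.node_covariance, dtype=float)
        C = self.node_covariance
        if C.shape != (self.n_nodes, self.n_nodes) or not np.allclose(C, C.T):
            raise ValueError("node_covariance must be a symmetric n_nodes x n_nodes matrix")
        # positive definiteness is what the Cholesky draw needs
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin <= 0:
            raise ValueError(
                f"node_covariance is not positive definite (min eigenvalue {eigmin:.3e})"
            )
        self.mediators = tuple(
            m if isinstance(m, MediatorSpec) else MediatorSpec(*m) for m in self.mediators
        )
        core = wm_core_slices(self.grid_shape)
        for m in self.mediators:
            if not all(0 <= c < s for c, s in zip(m.voxel, self.grid_shape)):
                raise ValueError(f"mediator voxel {m.voxel} outside the grid")
            if not all(sl.start <= c < sl.stop for c, sl in zip(m.voxel, core)):
                raise ValueError(f"mediator voxel {m.voxel} outside the WM core")
            if m.lag_samples >= self.n_timepoints / 4:
                raise ValueError("mediator lag must be < n_timepoints / 4")
            if max(m.driven_nodes) > self.n_nodes or min(m.driven_nodes) < 1:
                raise ValueError("driven_nodes must be valid 1-based node ids")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted mediators (the recovery target)."""

    mediator_voxels: list
    lags: list
    weights: list
    driven_nodes: list

    def __post_init__(self):
        n = len(self.mediator_voxels)
        if not (len(self.lags) == len(self.weights) == len(self.driven_nodes) == n):
            raise ValueError("truth fields must have one entry per mediator")
        if any(lag < 0 for lag in self.lags):
            raise ValueError("lags must be non-negative")

    @property
    def n_mediators(self) -> int:
        return len(self.mediator_voxels)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mediator_voxels": [list(v) for v in self.mediator_voxels],
                "lags": [int(x) for x in self.lags],
                "weights": [float(w) for w in self.weights],
                "driven_nodes": [list(d) for d in self.driven_nodes],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            [tuple(v) for v in d["mediator_voxels"]],
            d["lags"],
            d["weights"],
            [tuple(x) for x in d["driven_nodes"]],
        )


@dataclass
class Cohort:
    """Everything one synthetic study produces, in memory."""

    bold: list                      # per subject: 4D (x, y, z, t) float array
    gm_prob: list                   # per subject 3D probability maps
    wm_prob: list
    csf_prob: list
    node_labels: np.ndarray         # 3D int label volume (GM nodes, 1..n)
    node_table: dict                # id -> name
    tract_labels: np.ndarray        # 3D int label volume (toy WM tracts)
    tract_table: dict
    motion: list                    # per subject: (t, 6) motion table
    truth: SyntheticTruth
    config: SimulationConfig
    latent: list                    # per subject: (n_nodes, t + pad) latent draws
    latent_pad: int                 # samples of pre-roll in `latent`

    @property
    def tr_seconds(self) -> float:
        return self.config.tr_seconds

    @property
    def n_subjects(self) -> int:
        return len(self.bold)

    def node_latent(self, subject: int) -> np.ndarray:
        """The (n_nodes, n_timepoints) latent series the GM voxels carry."""
        return self.latent[subject][:, self.latent_pad:]


def default_node_covariance(n_nodes: int, driven=(1, 2, 3), r_within: float = 0.6,
                            r_between: float = 0.15) -> np.ndarray:
    """Compound-structure node covariance: a tightly coupled sub-network
    (the 1-based ``driven`` ids, clipped to the available nodes) with
    correlation ``r_within``, everything else at baseline ``r_between``."""
    C = np.full((n_nodes, n_nodes), r_between)
    idx = [i - 1 for i in driven if 1 <= i <= n_nodes]
    for a in idx:
        for b in idx:
            C[a, b] = r_within
    np.fill_diagonal(C, 1.0)
    return C


def wm_core_slices(grid_shape) -> tuple:
    """Index slices of the interior WM core (probability-1.0 WM)."""
    return tuple(slice(2, s - 3 + 1) for s in grid_shape)


def mediator_cluster(center, lag_samples, weight, driven_nodes, radius: int = 1) -> list:
    """Expand one mediator into the cube of voxels within ``radius`` of
    ``center``, all sharing the same lag, weight and driven node set.

    The neighborhood-averaged control signal used by the engagement core
    means a lone signal voxel is diluted across its 5x5x5 cube; real WM
    BOLD fluctuations span contiguous voxels, so the recovery
    experiments plant small clusters rather than isolated voxels.
    """
    cx, cy, cz = (int(c) for c in center)
    specs = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                specs.append(MediatorSpec((cx + dx, cy + dy, cz + dz),
                                          lag_samples, weight, tuple(driven_nodes)))
    return specs


# ---------------------------------------------------------------------------
# geometry

def build_geometry(config: SimulationConfig):
    """Label and probability volumes for the phantom (deterministic).

    Returns (node_labels, node_table, tract_labels, tract_table,
    gm_prob, wm_prob, csf_prob, wm_core_mask).
    """
    nx, ny, nz = config.grid_shape
    node_labels = np.zeros(config.grid_shape, dtype=np.int32)
    # GM nodes: strips along x on the z=0 face
    edges = np.linspace(0, nx, config.n_nodes + 1).astype(int)
    for i in range(config.n_nodes):
        node_labels[edges[i]:edges[i + 1], :, 0] = i + 1
    node_table = {i + 1: f"node_{i + 1:02d}" for i in range(config.n_nodes)}

    gm_prob = (node_labels > 0).astype(float)
    csf_prob = np.zeros(config.grid_shape)
    csf_prob[:, :, nz - 1] = 1.0

    core = wm_core_slices(config.grid_shape)
    wm_core = np.zeros(config.grid_shape, dtype=bool)
    wm_core[core] = True
    shell = np.zeros(config.grid_shape, dtype=bool)
    shell[tuple(slice(max(sl.start - 1, 0), sl.stop + 1) for sl in core)] = True
    shell &= ~wm_core
    shell[:, :, 0] = False          # keep the GM and CSF faces clean
    shell[:, :, nz - 1] = False
    wm_prob = np.zeros(config.grid_shape)
    wm_prob[wm_core] = 1.0
    wm_prob[shell] = 0.7

    # toy tract atlas: split the WM core into slabs along z
    tract_labels = np.zeros(config.grid_shape, dtype=np.int32)
    z0, z1 = core[2].start, core[2].stop
    cuts = np.linspace(z0, z1, config.n_tracts + 1).astype(int)
    for t in range(config.n_tracts):
        slab = np.zeros(config.grid_shape, dtype=bool)
        slab[:, :, cuts[t]:cuts[t + 1]] = True
        tract_labels[wm_core & slab] = t + 1
    tract_table = {t + 1: f"tract_{t + 1:02d}" for t in range(config.n_tracts)}

    return (node_labels, node_table, tract_labels, tract_table,
            gm_prob, wm_prob, csf_prob, wm_core)


# ---------------------------------------------------------------------------
# signals

def _ar1(rng, shape, ar1, sd):
    """Stationary AR(1) Gaussian noise with marginal standard deviation sd."""
    white = rng.standard_normal(shape)
    if ar1 == 0.0 or sd == 0.0:
        return sd * white
    from scipy.signal import lfilter
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2)
    out = lfilter([1.0], [1.0, -ar1], innov_sd * white, axis=-1)
    return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a full synthetic cohort. Identical config (incl. seed) gives
    bit-identical output."""
    (node_labels, node_table, tract_labels, tract_table,
     gm_prob, wm_prob, csf_prob, wm_core) = build_geometry(config)

    max_lag = max((m.lag_samples for m in config.mediators), default=0)
    pad = int(max_lag)
    T = config.n_timepoints
    chol = np.linalg.cholesky(config.node_covariance)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    bold, motion, latents = [], [], []
    gm_probs, wm_probs, csf_probs = [], [], []

    med_index = {m.voxel: m for m in config.mediators}

    for s in range(config.n_subjects):
        rng = np.random.default_rng(seeds[s])
        latent = chol @ rng.standard_normal((config.n_nodes, T + pad))
        latents.append(latent)
        lat = latent[:, pad:]                      # window seen by GM

        vol = np.zeros(config.grid_shape + (T,))
        # GM voxels: node latent + white voxel noise
        for i in range(1, config.n_nodes + 1):
            vox = node_labels == i
            n_vox = int(vox.sum())
            vol[vox] = lat[i - 1] + config.gm_voxel_noise_sd * rng.standard_normal((n_vox, T))
        # WM (core + shell) and CSF: AR(1) noise
        noisy = (wm_prob > 0) | (csf_prob > 0)
        vol[noisy] = _ar1(rng, (int(noisy.sum()), T), config.noise_ar1, config.noise_sd)
        # mediators: delayed weighted latent mean + fresh AR(1) noise
        for m in config.mediators:
            ids = [i - 1 for i in m.driven_nodes]
            drive = latent[ids].mean(axis=0)
            delayed = drive[pad - m.lag_samples: pad - m.lag_samples + T]
            vol[m.voxel] = m.weight * delayed + _ar1(
                rng, (T,), config.noise_ar1, config.noise_sd)
        bold.append(vol)

        # small-amplitude smooth random walk, 6 columns; not applied to volumes
        steps = config.motion_step_sd * rng.standard_normal((T, 6))
        motion.append(np.cumsum(steps, axis=0))

        gm_probs.append(gm_prob.copy())
        wm_probs.append(wm_prob.copy())
        csf_probs.append(csf_prob.copy())

    truth = SyntheticTruth(
        mediator_voxels=[m.voxel for m in config.mediators],
        lags=[m.lag_samples for m in config.mediators],
        weights=[m.weight for m in config.mediators],
        driven_nodes=[m.driven_nodes for m in config.mediators],
    )
    return Cohort(bold, gm_probs, wm_probs, csf_probs, node_labels, node_table,
                  tract_labels, tract_table, motion, truth, config, latents, pad)


# ---------------------------------------------------------------------------
# truth-based evaluation

def truth_engagement_ranks(truth: SyntheticTruth, engagement,
                           against: str = "all") -> "pd.DataFrame":
    """Percentile rank of each planted mediator's global engagement.

    ``engagement`` is one EngagementMap or a mapping delay -> map; the
    report has one row per (mediator, delay). ``percentile`` is the
    percent of comparison voxels whose global engagement is strictly
    below the mediator's (100 = top voxel). Empty truth gives an empty
    report.

    With ``against="all"`` (default) the comparison population is every
    in-mask WM voxel. With ``against="non_mediator"`` other planted
    mediator voxels are excluded: when the truth is a contiguous
    cluster, its members are all true positives and jointly occupy the
    top ranks, so ranking each against its own siblings understates the
    separation from the null voxels — the recovery question.
    """
    import pandas as pd

    if against not in ("all", "non_mediator"):
        raise ValueError("against must be 'all' or 'non_mediator'")
    if hasattr(engagement, "global_values"):
        maps = {engagement.delay_seconds: engagement}
    else:
        maps = dict(engagement)
    med_set = {tuple(v) for v in truth.mediator_voxels}

    rows = []
    for delay, emap in sorted(maps.items()):
        vals = emap.global_values
        if against == "non_mediator":
            is_med = np.array([tuple(v) in med_set for v in emap.voxel_index])
            pool = vals[~is_med]
        else:
            pool = vals
        for k, voxel in enumerate(truth.mediator_voxels):
            v = emap.value_at(voxel)   # raises KeyError if outside the map
            pct = 100.0 * np.mean(pool < v)
            rows.append({
                "mediator": k,
                "voxel": tuple(voxel),
                "lag_samples": truth.lags[k],
                "delay_seconds": float(delay),
                "engagement": v,
                "percentile": pct,
            })
    return pd.DataFrame(rows, columns=["mediator", "voxel", "lag_samples",
                                       "delay_seconds", "engagement", "percentile"])


# ---------------------------------------------------------------------------
# disk round trip (NIfTI-1 + plain text)

_AFFINE = np.diag([1.5, 1.5, 1.5, 1.0])   # nominal 1.5 mm grid


def write_cohort(cohort: Cohort, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in range(cohort.n_subjects):
        sub = out / f"sub-{s + 1:02d}"
        sub.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(cohort.bold[s].astype(np.float32), _AFFINE),
                 sub / "bold.nii.gz")
        for name, vol in (("gm_prob", cohort.gm_prob[s]), ("wm_prob", cohort.wm_prob[s]),
                          ("csf_prob", cohort.csf_prob[s])):
            nib.save(nib.Nifti1Image(vol.astype(np.float32), _AFFINE),
                     sub / f"{name}.nii.gz")
        np.savetxt(sub / "motion.txt", cohort.motion[s], fmt="%.8f")
    nib.save(nib.Nifti1Image(cohort.node_labels.astype(np.int16), _AFFINE),
             out / "node_labels.nii.gz")
    nib.save(nib.Nifti1Image(cohort.tract_labels.astype(np.int16), _AFFINE),
             out / "tract_labels.nii.gz")
    for name, table in (("node_labels.tsv", cohort.node_table),
                        ("tract_labels.tsv", cohort.tract_table)):
        with open(out / name, "w") as fh:
            for i, nm in sorted(table.items()):
                fh.write(f"{i}\t{nm}\n")
    (out / "truth.json").write_text(cohort.truth.to_json())
    (out / "sim_config.json").write_text(json.dumps({
        "grid_shape": list(cohort.config.grid_shape),
        "n_timepoints": cohort.config.n_timepoints,
        "tr_seconds": cohort.config.tr_seconds,
        "n_nodes": cohort.config.n_nodes,
        "n_subjects": cohort.config.n_subjects,
        "seed": cohort.config.seed,
    }, indent=2))
    return out


def load_cohort_arrays(in_dir, load_bold: bool = True, load_motion: bool = True):
    """Load the on-disk cohort back into plain arrays (no truth latents).

    Returns a dict with the same fields the pipeline stages need; the
    heavyweight 4D volumes and the motion tables can be skipped by the
    stages that do not use them.
    """
    src = Path(in_dir)
    subs = sorted(p for p in src.iterdir() if p.is_dir() and p.name.startswith("sub-"))
    if not subs:
        raise FileNotFoundError(f"no sub-* directories under {src}")
    out = {"bold": [], "gm_prob": [], "wm_prob": [], "csf_prob": [], "motion": []}
    for sub in subs:
        if load_bold:
            out["bold"].append(np.asarray(nib.load(sub / "bold.nii.gz").get_fdata()))
        for name in ("gm_prob", "wm_prob", "csf_prob"):
            out[name].append(np.asarray(nib.load(sub / f"{name}.nii.gz").get_fdata()))
        if load_motion:
            mot = sub / "motion.txt"
            if not mot.exists():
                raise FileNotFoundError(f"missing motion table for {sub.name}")
            out["motion"].append(np.loadtxt(mot))
    out["node_labels"] = np.asarray(
        nib.load(src / "node_labels.nii.gz").get_fdata()).astype(int)
    out["tract_labels"] = np.asarray(
        nib.load(src / "tract_labels.nii.gz").get_fdata()).astype(int)
    cfg = json.loads((src / "sim_config.json").read_text())
    out["tr_seconds"] = float(cfg["tr_seconds"])
    truth_file = src / "truth.json"
    out["truth"] = SyntheticTruth.from_json(truth_file.read_text()) if truth_file.exists() else None
    return out


load_cohort = load_cohort_arrays
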