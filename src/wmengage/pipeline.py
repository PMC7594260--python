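"""End-to-end orchestration over an on-disk cohort.

The pipeline is a chain of stages, each reading the previous stage's
files from a shared run directory and writing its own:

    masks -> prep -> compute -> group -> summarize

``run_pipeline`` executes the whole chain; the individual ``stage_*``
functions back the corresponding CLI subcommands, so a run can be
resumed or repeated stage by stage. Deterministic stages are
bit-identical across reruns with the same config and inputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import engagement as eng
from . import group as grp
from . import prep as prep_mod
from . import summary
from .masks import BinaryMask, LabelVolume, build_pb_mask, define_gm_nodes, \
    parcellate_tracts, split_wm_depth
from .simulate import load_cohort_arrays
from .types import EngagementMap

__all__ = ["RunConfig", "run_pipeline", "PipelineError",
           "stage_masks", "stage_prep", "stage_compute", "stage_group",
           "stage_summarize"]

_AFFINE = np.diag([1.5, 1.5, 1.5, 1.0])


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and offending subject."""

    def __init__(self, stage, message, subject=None):
        self.stage = stage
        self.subject = subject
        where = f"stage '{stage}'" + (f", subject {subject}" if subject is not None else "")
        super().__init__(f"{where}: {message}")


@dataclass
class RunConfig:
    """All fixed constants of a run, in one serializable place."""

    cohort_dir: str = ""
    out_dir: str = "run"
    wm_tight_threshold: float = 0.95
    gm_threshold: float = 0.6
    wm_loose_threshold: float = 0.5
    band_hz: tuple = (0.01, 0.1)
    delays_seconds: tuple = (0.0, 2.0, 4.0, 6.0)
    neighborhood: int = 5
    compcor_k: int = 5
    drift_order: int = 1
    fdr_q: float = 0.01
    split_seed: int = 0
    deep_tract_ids: tuple = (2,)

    def __post_init__(self):
        self.band_hz = tuple(float(b) for b in self.band_hz)
        self.delays_seconds = tuple(float(d) for d in self.delays_seconds)
        self.deep_tract_ids = tuple(int(i) for i in self.deep_tract_ids)
        for name in ("wm_tight_threshold", "gm_threshold", "wm_loose_threshold", "fdr_q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if not (0 < self.band_hz[0] < self.band_hz[1]):
            raise ValueError("band_hz must be an increasing positive pair")
        if self.neighborhood < 1 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be an odd positive integer")
        if self.compcor_k < 0 or self.drift_order < 0:
            raise ValueError("compcor_k and drift_order must be >= 0")
        if any(d < 0 for d in self.delays_seconds):
            raise ValueError("delays must be non-negative")

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["delays_seconds"] = list(self.delays_seconds)
        d["deep_tract_ids"] = list(self.deep_tract_ids)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**yaml.safe_load(text))


def _save(vol, path, dtype=np.float32):
    nib.save(nib.Nifti1Image(np.asarray(vol).astype(dtype), _AFFINE), path)


def _load(path) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata())


def _log(out: Path, stage: str, **info):
    path = out / "provenance.json"
    prov = json.loads(path.read_text()) if path.exists() else {"stages": []}
    prov["stages"].append({"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                           **info})
    path.write_text(json.dumps(prov, indent=2))


def _subject_dirs(cohort_dir) -> list:
    subs = sorted(p for p in Path(cohort_dir).iterdir()
                  if p.is_dir() and p.name.startswith("sub-"))
    if not subs:
        raise PipelineError("load", f"no sub-* directories in {cohort_dir}")
    return subs


# ---------------------------------------------------------------------------
# stages

def stage_masks(config: RunConfig) -> Path:
    """Population masks, node definitions, tract parcellation, depth split."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cohort = load_cohort_arrays(config.cohort_dir, load_bold=False,
                                    load_motion=False)
        wm_tight = build_pb_mask(cohort["wm_prob"], config.wm_tight_threshold,
                                 label="PB_WM_tight")
        gm_mask = build_pb_mask(cohort["gm_prob"], config.gm_threshold, label="PB_GM")
        nodes = define_gm_nodes(gm_mask, LabelVolume(cohort["node_labels"]))
        tract_atlas = LabelVolume(cohort["tract_labels"])
        tracts = parcellate_tracts(wm_tight, tract_atlas)
        superficial, deep = split_wm_depth(cohort["wm_prob"], tract_atlas,
                                           config.deep_tract_ids,
                                           loose_threshold=config.wm_loose_threshold)
    except (ValueError, FileNotFoundError) as e:
        raise PipelineError("masks", str(e)) from e
    mdir = out / "masks"
    mdir.mkdir(exist_ok=True)
    _save(wm_tight.values, mdir / "pb_wm_tight.nii.gz", np.uint8)
    _save(gm_mask.values, mdir / "pb_gm.nii.gz", np.uint8)
    _save(nodes.values, mdir / "nodes.nii.gz", np.int16)
    _save(tracts.values, mdir / "tracts.nii.gz", np.int16)
    _save(superficial.values, mdir / "superficial.nii.gz", np.uint8)
    _save(deep.values, mdir / "deep.nii.gz", np.uint8)
    with open(mdir / "tracts.tsv", "w") as fh:
        for i, nm in sorted(tracts.table.items()):
            fh.write(f"{i}\t{nm}\n")
    _log(out, "masks", wm_tight_voxels=wm_tight.n_voxels,
         gm_voxels=gm_mask.n_voxels, superficial_voxels=superficial.n_voxels,
         deep_voxels=deep.n_voxels)
    return mdir


def stage_prep(config: RunConfig) -> Path:
    """Per-subject confound regression, drift removal, fALFF, bandpass,
    standardization; writes cleaned 4D volumes and fALFF maps."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subs = _subject_dirs(config.cohort_dir)
    for s, sub in enumerate(subs):
        try:
            motion_file = sub / "motion.txt"
            if not motion_file.exists():
                raise FileNotFoundError(f"missing motion table {motion_file}")
            vol = _load(sub / "bold.nii.gz")
            gm_p = _load(sub / "gm_prob.nii.gz")
            wm_p = _load(sub / "wm_prob.nii.gz")
            csf_p = _load(sub / "csf_prob.nii.gz")
            tissue = (gm_p > 0) | (wm_p > 0) | (csf_p > 0)
            tr = json.loads((Path(config.cohort_dir) / "sim_config.json").read_text()
                            )["tr_seconds"] if (Path(config.cohort_dir) / "sim_config.json").exists() else 2.0
            clean, falff, prov = prep_mod.preprocess_subject(
                vol[tissue], tr, motion6=np.loadtxt(motion_file),
                compcor_ts=vol[csf_p > 0.95], compcor_k=config.compcor_k,
                low_hz=config.band_hz[0], high_hz=config.band_hz[1],
                drift_order=config.drift_order)
        except (ValueError, FileNotFoundError, OSError) as e:
            raise PipelineError("prep", str(e), subject=sub.name) from e
        clean_vol = np.zeros_like(vol)
        clean_vol[tissue] = clean
        fvol = np.full(vol.shape[:3], np.nan)
        fvol[tissue] = falff
        sdir = out / sub.name
        sdir.mkdir(exist_ok=True)
        _save(clean_vol, sdir / "clean.nii.gz")
        _save(fvol, sdir / "falff.nii.gz")
        (sdir / "prep_provenance.json").write_text(
            json.dumps({"tr_seconds": tr, **prov}, indent=2))
    _log(out, "prep", n_subjects=len(subs))
    return out


def stage_compute(config: RunConfig) -> Path:
    """Per-subject, per-delay engagement maps (raw and percent-rescaled)."""
    out = Path(config.out_dir)
    mdir = out / "masks"
    try:
        wm_tight = BinaryMask(_load(mdir / "pb_wm_tight.nii.gz") > 0.5, "PB_WM_tight")
        nodes = _load(mdir / "nodes.nii.gz").astype(int)
    except FileNotFoundError as e:
        raise PipelineError("compute", f"masks stage outputs missing: {e}") from e
    subs = _subject_dirs(config.cohort_dir)
    for sub in subs:
        sdir = out / sub.name
        try:
            prov = json.loads((sdir / "prep_provenance.json").read_text())
            clean_vol = _load(sdir / "clean.nii.gz")
            node_ts = eng.extract_node_timeseries(clean_vol, nodes,
                                                  tr_seconds=prov["tr_seconds"])
            maps = eng.engagement_map(clean_vol, node_ts, wm_tight,
                                      delays=config.delays_seconds,
                                      tr_seconds=prov["tr_seconds"],
                                      size=config.neighborhood)
        except (ValueError, FileNotFoundError, KeyError) as e:
            raise PipelineError("compute", str(e), subject=sub.name) from e
        for d, m in maps.items():
            _save(m.global_volume(), sdir / f"engagement_raw_delay{d:g}s.nii.gz")
            rm = eng.rescale_percent(m)
            _save(rm.global_volume(), sdir / f"engagement_delay{d:g}s.nii.gz")
            _save(np.stack([  # local maps as a 4D stack, one volume per node
                _scatter(rm.mask, rm.voxel_index, rm.local_values[:, i])
                for i in range(rm.local_values.shape[1])], axis=-1),
                sdir / f"engagement_local_delay{d:g}s.nii.gz")
    _log(out, "compute", delays=list(config.delays_seconds),
         neighborhood=config.neighborhood)
    return out


def _scatter(mask, voxel_index, values) -> np.ndarray:
    vol = np.full(mask.shape, np.nan)
    vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return vol


def _load_maps(out: Path, delay: float, rescaled=True) -> list:
    mask = _load(out / "masks" / "pb_wm_tight.nii.gz") > 0.5
    name = f"engagement_delay{delay:g}s.nii.gz" if rescaled \
        else f"engagement_raw_delay{delay:g}s.nii.gz"
    maps = []
    for sdir in sorted(out.glob("sub-*")):
        vol = _load(sdir / name)
        voxel_index = np.argwhere(mask & np.isfinite(vol))
        vals = vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]]
        maps.append(EngagementMap(
            global_values=vals, local_values=np.zeros((vals.size, 1)),
            mask=mask, voxel_index=voxel_index, delay_seconds=delay,
            rescaled=rescaled))
    return maps


def stage_group(config: RunConfig) -> dict:
    """Voxel-wise one-sample t-tests with BH-FDR, plus the seeded
    split-half reproducibility of the first delay's maps."""
    out = Path(config.out_dir)
    gdir = out / "group"
    gdir.mkdir(parents=True, exist_ok=True)
    summary_json = {}
    for d in config.delays_seconds:
        try:
            maps = _load_maps(out, d)
            stat = grp.one_sample_ttest(maps, q=config.fdr_q)
        except (ValueError, FileNotFoundError) as e:
            raise PipelineError("group", str(e)) from e
        _save(stat.volume("t"), gdir / f"tmap_delay{d:g}s.nii.gz")
        _save(stat.volume("p"), gdir / f"pmap_delay{d:g}s.nii.gz")
        _save(stat.significance_mask().values, gdir / f"sig_delay{d:g}s.nii.gz",
              np.uint8)
        summary_json[f"{d:g}"] = {"n_subjects": stat.n_subjects, "df": stat.df,
                                  "q": config.fdr_q,
                                  "n_significant": int(stat.significant.sum())}
    maps0 = _load_maps(out, config.delays_seconds[0])
    if len(maps0) >= 4:
        _, _, r, ci, split = grp.split_half_reproducibility(maps0, seed=config.split_seed)
        summary_json["split_half"] = {"delay": config.delays_seconds[0], "r": r,
                                      "ci": list(ci), "seed": config.split_seed, **split}
    (gdir / "summary.json").write_text(json.dumps(summary_json, indent=2))
    _log(out, "group", fdr_q=config.fdr_q)
    return summary_json


def stage_summarize(config: RunConfig) -> Path:
    """Tract-level counts, tract fALFF, engagement-fALFF correlation and
    the superficial-vs-deep comparison."""
    import pandas as pd
    out = Path(config.out_dir)
    mdir = out / "masks"
    try:
        tract_vol = _load(mdir / "tracts.nii.gz").astype(int)
        table = {}
        for line in (mdir / "tracts.tsv").read_text().splitlines():
            i, nm = line.split("\t")
            table[int(i)] = nm
        tracts = LabelVolume(tract_vol, table)
        wm_tight = BinaryMask(_load(mdir / "pb_wm_tight.nii.gz") > 0.5)
        superficial = BinaryMask(_load(mdir / "superficial.nii.gz") > 0.5, "superficial")
        deep = BinaryMask(_load(mdir / "deep.nii.gz") > 0.5, "deep")
        falff_vols = [_load(sdir / "falff.nii.gz") for sdir in sorted(out.glob("sub-*"))]
        falff_df = summary.falff_by_tract(falff_vols, tracts)
        frames = []
        for d in config.delays_seconds:
            sig = BinaryMask(_load(out / "group" / f"sig_delay{d:g}s.nii.gz") > 0.5)
            c = summary.tract_counts(sig, tracts)
            c["delay_seconds"] = d
            frames.append(c)
        counts_df = pd.concat(frames, ignore_index=True)
        rescaled = {d: _load_maps(out, d) for d in config.delays_seconds}
        depth_df = summary.depth_comparison(rescaled, superficial & wm_tight,
                                            deep & wm_tight)
    except (ValueError, FileNotFoundError) as e:
        raise PipelineError("summarize", str(e)) from e
    sdir = out / "summary"
    sdir.mkdir(exist_ok=True)
    counts_df.to_csv(sdir / "tract_counts.tsv", sep="\t", index=False)
    falff_df.to_csv(sdir / "tract_falff.tsv", sep="\t", index=False)
    depth_df.drop(columns=["subject_superficial", "subject_deep"]).to_csv(
        sdir / "depth_comparison.tsv", sep="\t", index=False)
    corr = {}
    for d in config.delays_seconds:
        cd = counts_df[counts_df["delay_seconds"] == d]
        merged = cd.merge(falff_df, on=["tract_id", "tract_name"])
        try:
            r, p, n = summary.engagement_falff_correlation(
                merged["n_significant"], merged["falff_mean"])
            corr[f"{d:g}"] = {"r": r, "p": p, "n_tracts": n}
        except ValueError as e:
            corr[f"{d:g}"] = {"error": str(e)}
    (sdir / "engagement_falff.json").write_text(json.dumps(corr, indent=2))
    _log(out, "summarize", n_tracts=int(len(falff_df)))
    return sdir


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order on one cohort directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    _log(out, "start", config=yaml.safe_load(config.to_yaml()))
    stage_masks(config)
    stage_prep(config)
    stage_compute(config)
    stage_group(config)
    stage_summarize(config)
    return out
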