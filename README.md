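# wmengage

Functional **engagement** of white-matter (WM) voxels in resting-state
gray-matter (GM) brain networks.

Resting-state fMRI network models are built from pairwise correlations
between GM regions; BOLD fluctuations in WM are usually discarded as
noise. `wmengage` implements the opposite question: *how much does a
network of GM nodes depend on the signal carried by each WM voxel?*
For every WM voxel *x* it compares the full Pearson connectivity matrix
*M* of the GM node series with the first-order partial correlation
matrix *M′ₓ* in which *x*'s signal has been regressed out of every node
pair,

```
r_ij·x = (r_ij − r_ix r_jx) / √((1 − r_ix²)(1 − r_jx²))
```

and summarizes the loss of connectivity as

* **global engagement**  G(M) − G(M′ₓ), where G sums the connectivity
  over all node pairs, and
* **local engagement**  L_i(M) − L_i(M′ₓ) per node *i*, where L_i
  averages node *i*'s edges.

Because the WM hemodynamic response lags GM, the control signal — the
average over the 5×5×5 WM-restricted cube around *x* — is shifted
forward by an assumed delay *t* ∈ {0, 2, 4, 6} s before the partial
correlation, and one engagement map is produced per delay. Per-subject
maps are rescaled to percent difference from their mean, tested
voxel-wise against zero across subjects (one-sample *t*), and
thresholded with Benjamini–Hochberg FDR. Tract-level counts, a
superficial/deep WM comparison, split-half reproducibility and an
engagement-vs-fALFF correlation complete the group analysis.

The package is self-validating: `wmengage.simulate` generates full
synthetic cohorts (NIfTI volumes, tissue probability maps, node/tract
atlases, motion tables) with *planted* WM mediators of known lag and
strength, and `wmengage.studies` runs recovery experiments against
that ground truth.

## Worked example

`examples/02_engagement_map.py` plants a 27-voxel mediator cluster
whose signal lags the GM nodes by 4 s, runs the pipeline at all four
assumed delays on 5 subjects, and prints:

```
WM voxels evaluated: 1000, subjects: 5
assumed delay ->  mediator engagement | map median (null level)
    0 s      ->                -0.032 |  -0.0192
    2 s      ->                 0.325 |   0.0073
    4 s      ->                 0.954 |   0.0173
    6 s      ->                 0.510 |   0.0143
```

The mediator's group-mean connectivity drop peaks at the assumed delay
matching its planted 4 s lag, while the map median (the null level)
stays near zero. `examples/03_group_recovery.py` continues to group
inference: the cluster center outranks every non-planted voxel
(percentile 100 vs the null population) and survives FDR q = 0.01 with
a group *t* around 40 on 10 subjects. The other examples cover cohort
generation and the tract/depth summaries.

## Command line

A thin CLI wraps the library for shell use:

```bash
wm-engage simulate --config sim.yaml --out cohort/ --seed 1
wm-engage run --cohort cohort/ --out run/ --q 0.01 --delays 0,2,4,6
# or stage by stage: masks, prep, compute, group, summarize
wm-engage validate --out report.json --seed 1
```

`run` writes every intermediate (masks, cleaned volumes, fALFF maps,
per-delay engagement maps, t/p/significance volumes, tract and depth
tables) plus a provenance log into the run directory.

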