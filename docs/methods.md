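# Methods

## The engagement measure

Let the GM network be defined by n node time series (mean BOLD signal
over each atlas region restricted to the population GM mask). The full
connectivity matrix M holds the pairwise Pearson correlations r_ij.
For a WM voxel x with control series c, the first-order partial
correlation

    r_ij·x = (r_ij − r_ix r_jx) / sqrt((1 − r_ix²)(1 − r_jx²))

is algebraically identical to correlating the residuals of each node
series after regressing c out (a property the test suite verifies to
1e-10 against an explicit residualization oracle). Global engagement is
G(M) − G(M′ₓ) with G(M) = Σ_{i<j} M_ij; local engagement for node i is
the drop in L_i, reported in mean form (sum form is sum = mean·(n−1);
the two differ by a constant factor that cancels under percent
rescaling and t-testing, and both are exposed). G and L keep the sign
of connectivity — no absolute values — so an *increase* in negative
coupling registers as negative engagement; this polarity blindness is a
known limitation of the summed-connectivity metric.

### Control signal

The control for voxel x is the mean over the 5×5×5 axis-aligned cube
centered at x, intersected with the tight WM mask (center included,
cube clipped at the grid edges). Averaging boosts voxel SNR at the cost
of spatial resolution: the engagement map is intrinsically smooth at
the neighborhood scale, since adjacent voxels share almost their whole
cube.

### Delay compensation

WM hemodynamics lag GM, so the control is *advanced* by an assumed
delay t ∈ {0, 2, 4, 6} s before the partial correlation: the control
sample at index k is replaced by the sample at k + t/TR, and both the
control and the node series are truncated to their first T − t/TR
overlapping samples. Delays must be whole multiples of TR (no
sub-sample interpolation). M is recomputed on each delay's truncated
window, so M and M′ₓ always come from identical samples — otherwise the
difference would confound truncation with engagement. The generator and
the core share one lag convention (a mediator with lag k reproduces the
latent signal k samples *later* than GM; the forward shift undoes
exactly this), asserted by a round-trip test.

### Rescaling and group inference

Per subject and delay, the map is rescaled to percent difference from
its in-mask mean, e′ₓ = 100·(eₓ − ē)/|ē|, which gives the map a unit
and removes inter-individual global scale; dividing by |ē| preserves
the sign of engagement when ē > 0. A map whose mean is within 1e-12 of
zero cannot be meaningfully rescaled and is rejected with a diagnostic.
Note one consequence of mean-centering: when a strong engaged cluster
exists, the remaining voxels sit systematically below the map mean, so
a two-sided group test marks them significantly *negative*; the
figures of interest are the positive-t (engaged) voxels.

Group maps use a voxel-wise one-sample t-test (two-sided, df = n−1)
across subjects, with Benjamini–Hochberg FDR within the analysis mask
(the tight WM mask). Voxels with zero cross-subject variance have no
defined t; they are flagged and excluded from the FDR step rather than
silently zeroed. Split-half reproducibility draws a seeded random
partition into ⌊n/2⌋ + ⌈n/2⌉ subjects and reports the Pearson r between
the half-mean maps with a Fisher-z 95% CI (the CI method is our choice;
the quantity is standard). A permutation null band (random re-splits
with random per-subject sign flips) calibrates what |r| pure noise
produces.

## Preprocessing

Fixed order, logged in a provenance record:

1. confound regression — Friston-24 motion expansion
   [R(t), R(t−1), R(t)², R(t−1)²] plus aCompCor: the top-k principal
   component time courses of the demeaned CSF-ROI signals (k = 5 by
   default; the component count, like the filter family and drift
   order, is a package default, configurable);
2. drift correction — removal of a first-order polynomial (order
   configurable);
3. fALFF snapshot — taken *before* bandpassing, as the ratio of the
   power spectrum summed over the closed band [0.01, 0.1] Hz to the
   power over all positive frequencies, DC excluded, from the
   unwindowed full-length DFT;
4. bandpass — zero-phase 4th-order Butterworth (forward–backward),
   0.01–0.1 Hz; zero phase matters because a phase-shifting filter
   would corrupt the delay analysis;
5. standardization — zero mean, unit variance with the n−1 divisor.

## The synthetic cohort generator

The phantom is a cuboid grid: GM nodes are disjoint strips on the z = 0
face, CSF is the opposite face, WM is an interior core of probability
1.0 wrapped in a 1-voxel shell at probability 0.7 (so the 0.95 / 0.6 /
0.5 mask thresholds all select different voxel sets). The WM core is
sliced into slabs to provide a toy tract atlas; the middle slab doubles
as the "deep WM" structure set for the depth split.

Per subject, an n-node latent series is drawn i.i.d. over time from a
configurable node covariance (default: a compound structure with a
tightly coupled sub-network at r = 0.6 over baseline 0.15). GM voxels
carry their node's latent series plus white voxel noise (sd 0.5); WM
and CSF voxels carry stationary AR(1) Gaussian noise (coefficient 0.3,
sd 0.5 by default) — autocorrelated rather than white so that
bandpassing and fALFF behave nontrivially. A planted mediator voxel
carries weight·(mean of its driven nodes' latent series), reproduced
lag_samples later than GM, plus its own AR(1) noise. Motion tables are
smooth small-amplitude random walks (6 columns); they exercise the
Friston-24 regression but are not applied to the volumes. Identical
config and seed give bit-identical cohorts.

What the generator does *not* emulate: hemodynamic response shapes
(signals are broadband rather than HRF-smoothed), physiological
waveforms, spatial smoothing, scanner artifacts, and realistic
anatomy. Passing recovery tests therefore demonstrates the estimator's
correctness and calibration under a known ground truth, not performance
on real acquisitions.

### Mediator clusters, not single voxels

The recovery experiments plant mediators as 3×3×3 clusters
(`mediator_cluster`). This is deliberate: the 5×5×5 neighborhood
average dilutes an isolated single-voxel signal ~125-fold and makes its
engagement indistinguishable from its neighbors', so a single planted
voxel tests the noise floor rather than the method. Real WM BOLD
fluctuations — the very reason the neighborhood average exists — extend
over contiguous voxels. A consequence is that the cluster members
jointly occupy the top of the ranking; recovery is therefore scored as
(a) the top 1% of the group-mean map consists entirely of planted
voxels and (b) the cluster center survives FDR q = 0.01, and the
center's percentile rank is additionally reported against the
non-mediator (null) population.

### Study conditions

Recovery, lag and split-half studies run on a 14×14×14 grid whose WM
core holds 10³ = 1000 voxels — the smallest size at which a top-1% rank
(top 10 voxels) is meaningful while each repetition stays around a
second of CPU. They use 200 timepoints at TR 2 s, 5 nodes, 10 subjects
(20 for split-half), mediator weight 0.9 (0.8 for split-half), AR(1)
0.3 noise at sd 0.5. The null-calibration study uses a 10×10×10 grid
(216 WM voxels). The default `SimulationConfig` is the smaller 8×8×8
toy used by the pipeline round-trip tests.

## Numerical choices and degenerate cases

- Correlations are computed in double precision; partial correlations
  clip to [−1, 1] and reject controls with |r_ix| ≥ 1 − 1e-10, naming
  the node. In `engagement_map`, per-voxel failures (collinear or
  constant controls) are recorded in `failed_voxels` and those voxels
  are dropped, never silently zeroed.
- Mask thresholds are strict (">"): a subject-mean probability exactly
  at the threshold is excluded.
- The neighborhood box sums use a separable uniform filter with zero
  padding, which is exactly the edge-clipped cube; agreement with a
  brute-force 125-voxel loop is tested.
- A paired depth comparison with a constant nonzero difference has no
  sample variance; it is reported as an exact difference with p at the
  machine floor rather than NaN.
- In the null-calibration test the voxel-wise exceedance fraction is
  compared against a binomial bound with a conservative effective n of
  disjoint 5³ blocks, because neighborhood sharing makes adjacent
  engagement values almost identical.
- Very small grids degenerate honestly: on a 7³ grid every WM voxel's
  cube covers the entire 3³ core, all controls coincide, and the map is
  constant — downstream stages reject it with a clear error.

## Known limitations

Engagement ignores connectivity polarity and matrix pattern changes
(only the summed magnitude is compared); only one control series is
partialled at a time (no joint higher-order partial correlations);
delays are multiples of TR; and the percent rescaling is undefined for
maps with near-zero mean, which genuinely occurs for pure-noise
cohorts at some sizes. The motion regressors, being low-frequency-rich
random walks, can remove an appreciable share of the narrow passband
for an individual subject; group-level estimates are robust to this,
single-subject maps less so.
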