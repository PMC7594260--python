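"""Generator correctness: determinism, signal identities, lag convention."""

import numpy as np
import pytest

from wmengage.simulate import (MediatorSpec, SimulationConfig, SyntheticTruth,
                               build_geometry, generate_cohort, load_cohort,
                               mediator_cluster, truth_engagement_ranks,
                               wm_core_slices, write_cohort)
from wmengage.types import EngagementMap


def _single_mediator_config(lag, weight, noise_sd, seed, n_timepoints=200):
    return SimulationConfig(grid_shape=(8, 8, 8), n_timepoints=n_timepoints,
                            n_subjects=1, seed=seed, noise_sd=noise_sd,
                            mediators=[MediatorSpec((3, 3, 3), lag, weight, (1,))])


def test_seeded_determinism():
    cfg = SimulationConfig(grid_shape=(7, 7, 7), n_timepoints=60, n_subjects=3, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(SimulationConfig(grid_shape=(7, 7, 7), n_timepoints=60,
                                         n_subjects=3, seed=42))
    for s in range(3):
        np.testing.assert_array_equal(a.bold[s], b.bold[s])
        np.testing.assert_array_equal(a.motion[s], b.motion[s])
    c = generate_cohort(SimulationConfig(grid_shape=(7, 7, 7), n_timepoints=60,
                                         n_subjects=3, seed=43))
    assert not np.array_equal(a.bold[0], c.bold[0])


def test_noiseless_mediator_reproduces_latent_exactly():
    """Weight 1, lag 0, zero noise: the mediator voxel IS node 1's latent."""
    cfg = _single_mediator_config(lag=0, weight=1.0, noise_sd=0.0, seed=3)
    cohort = generate_cohort(cfg)
    np.testing.assert_allclose(cohort.bold[0][3, 3, 3], cohort.node_latent(0)[0],
                               atol=1e-12)


def test_lag_convention_monte_carlo():
    """The mediator reproduces the latent k samples later: advancing the
    voxel series by k maximizes its correlation with the driving latent,
    across 50 independent seeds."""
    k_true = 2
    wins = 0
    for seed in range(50):
        cfg = _single_mediator_config(lag=k_true, weight=0.8, noise_sd=0.5, seed=seed)
        cohort = generate_cohort(cfg)
        v = cohort.bold[0][3, 3, 3]
        drive = cohort.node_latent(0)[0]
        T = v.size
        corrs = {k: np.corrcoef(v[k:], drive[:T - k])[0, 1] for k in range(4)}
        if max(corrs, key=corrs.get) == k_true:
            wins += 1
    assert wins == 50


def test_gm_voxels_carry_node_latent_plus_noise():
    cfg = SimulationConfig(grid_shape=(8, 8, 8), n_timepoints=100, n_subjects=1,
                           gm_voxel_noise_sd=0.25, seed=9)
    cohort = generate_cohort(cfg)
    lat = cohort.node_latent(0)
    for i in range(1, cfg.n_nodes + 1):
        vox = cohort.bold[0][cohort.node_labels == i]
        resid = vox - lat[i - 1]
        # residual should be white voxel noise of the configured scale
        assert abs(resid.std() - 0.25) < 0.05
        r = np.corrcoef(vox.mean(axis=0), lat[i - 1])[0, 1]
        assert r > 0.95


def test_geometry_masks_and_thresholds():
    cfg = SimulationConfig(grid_shape=(10, 10, 10), seed=0)
    (_, _, tracts, _, gm, wm, csf, core) = build_geometry(cfg)
    assert set(np.unique(wm)) == {0.0, 0.7, 1.0}
    # threshold semantics the mask builder will exercise
    assert ((wm > 0.95) == core).all()
    assert (wm > 0.5).sum() > core.sum()          # shell enters the loose mask
    assert ((gm > 0) & (wm > 0)).sum() == 0       # tissues disjoint at prob 1
    assert set(np.unique(tracts[core])) == {1, 2, 3}
    assert (tracts[~core] == 0).all()


def test_invalid_configs_rejected():
    bad_cov = np.array([[1.0, 2.0], [2.0, 1.0]])   # indefinite
    with pytest.raises(ValueError, match="positive definite"):
        SimulationConfig(n_nodes=2, node_covariance=bad_cov)
    with pytest.raises(ValueError, match="outside the grid"):
        SimulationConfig(mediators=[MediatorSpec((99, 0, 0), 0, 0.5, (1,))])
    with pytest.raises(ValueError, match="lag"):
        SimulationConfig(n_timepoints=40, mediators=[MediatorSpec((3, 3, 3), 20, 0.5, (1,))])
    with pytest.raises(ValueError):
        MediatorSpec((3, 3, 3), 0, 1.5, (1,))


def test_mediator_cluster_expands_cube():
    specs = mediator_cluster((5, 5, 5), 2, 0.9, (1, 2), radius=1)
    assert len(specs) == 27
    assert all(s.lag_samples == 2 and s.weight == 0.9 for s in specs)
    assert MediatorSpec((4, 4, 4), 2, 0.9, (1, 2)) in specs


def _flat_map(values, grid=(6, 6, 6)):
    mask = np.zeros(grid, bool)
    mask[1:4, 1, 1] = True
    ix = np.argwhere(mask)
    return EngagementMap(global_values=np.asarray(values, float),
                         local_values=np.zeros((len(values), 2)), mask=mask,
                         voxel_index=ix, delay_seconds=0.0)


def test_truth_ranks_empty_and_errors():
    empty = SyntheticTruth([], [], [], [])
    report = truth_engagement_ranks(empty, _flat_map([1.0, 2.0, 3.0]))
    assert report.empty
    outside = SyntheticTruth([(5, 5, 5)], [0], [0.9], [(1,)])
    with pytest.raises(KeyError):
        truth_engagement_ranks(outside, _flat_map([1.0, 2.0, 3.0]))


def test_truth_ranks_percentile_definition():
    truth = SyntheticTruth([(3, 1, 1)], [0], [0.9], [(1,)])
    report = truth_engagement_ranks(truth, _flat_map([1.0, 2.0, 5.0]))
    assert report.loc[0, "percentile"] == pytest.approx(100 * 2 / 3)


def test_cohort_disk_round_trip(tmp_path, tiny_cohort):
    out = write_cohort(tiny_cohort, tmp_path / "cohort")
    back = load_cohort(out)
    assert len(back["bold"]) == tiny_cohort.n_subjects
    np.testing.assert_allclose(back["bold"][0], tiny_cohort.bold[0], rtol=1e-6)
    np.testing.assert_array_equal(back["node_labels"], tiny_cohort.node_labels)
    np.testing.assert_allclose(back["motion"][1], tiny_cohort.motion[1], atol=1e-8)
    assert back["truth"].n_mediators == 0
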