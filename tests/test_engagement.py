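"""The engagement core: node extraction, neighborhood controls, delay
shifts, partial correlation, the G/L metrics and the map composition."""

import numpy as np
import pytest

from wmengage import engagement as eng
from wmengage.masks import BinaryMask
from wmengage.types import TimeSeriesMatrix

TR = 2.0


# ---------------------------------------------------------------------------
# node extraction

def test_extract_node_timeseries_single_voxel_and_oracle(rng):
    vol = rng.standard_normal((5, 5, 5, 40))
    labels = np.zeros((5, 5, 5), int)
    labels[0, 0, 0] = 1
    labels[2:4, 2, 2] = 2
    ts = eng.extract_node_timeseries(vol, labels, tr_seconds=TR)
    np.testing.assert_array_equal(ts.unit_ids, [1, 2])
    np.testing.assert_allclose(ts.values[0], vol[0, 0, 0])
    np.testing.assert_allclose(ts.values[1], vol[labels == 2].mean(axis=0))


def test_extract_node_timeseries_opposite_voxels_cancel(rng):
    vol = np.zeros((3, 3, 3, 20))
    x = rng.standard_normal(20)
    vol[0, 0, 0] = x
    vol[0, 0, 1] = -x
    labels = np.zeros((3, 3, 3), int)
    labels[0, 0, :2] = 1
    ts = eng.extract_node_timeseries(vol, labels)
    np.testing.assert_allclose(ts.values[0], 0.0, atol=1e-14)


def test_extract_node_timeseries_random_oracle(rng):
    vol = rng.standard_normal((6, 6, 6, 30))
    labels = rng.integers(0, 4, size=(6, 6, 6))
    ts = eng.extract_node_timeseries(vol, labels)
    for r, i in enumerate(ts.unit_ids):
        np.testing.assert_allclose(ts.values[r], vol[labels == i].mean(axis=0))


# ---------------------------------------------------------------------------
# neighborhood average

def test_neighborhood_isolated_and_constant(rng):
    vol = rng.standard_normal((7, 7, 7, 25))
    mask = np.zeros((7, 7, 7), bool)
    mask[3, 3, 3] = True                       # isolated WM voxel
    np.testing.assert_allclose(eng.neighborhood_average(vol, mask, (3, 3, 3)),
                               vol[3, 3, 3])
    mask[:] = True
    const = np.ones((7, 7, 7, 25)) * 4.2
    np.testing.assert_allclose(eng.neighborhood_average(const, mask, (2, 2, 2)), 4.2)


@pytest.mark.parametrize("voxel", [(3, 3, 3), (0, 0, 0), (6, 1, 5)])
def test_neighborhood_matches_brute_force(rng, voxel):
    """Cube clipped at edges, restricted to WM, center included."""
    vol = rng.standard_normal((7, 7, 7, 15))
    mask = rng.uniform(size=(7, 7, 7)) > 0.4
    mask[voxel] = True
    acc, cnt = np.zeros(15), 0
    for dx in range(-2, 3):
        for dy in range(-2, 3):
            for dz in range(-2, 3):
                p = (voxel[0] + dx, voxel[1] + dy, voxel[2] + dz)
                if all(0 <= c < 7 for c in p) and mask[p]:
                    acc += vol[p]
                    cnt += 1
    np.testing.assert_allclose(eng.neighborhood_average(vol, mask, voxel),
                               acc / cnt, atol=1e-10)


def test_neighborhood_average_all_agrees_with_per_voxel(rng):
    vol = rng.standard_normal((6, 6, 6, 12))
    mask = rng.uniform(size=(6, 6, 6)) > 0.3
    controls, ix = eng.neighborhood_average_all(vol, mask)
    for row, voxel in zip(controls, ix):
        np.testing.assert_allclose(row, eng.neighborhood_average(vol, mask, voxel),
                                   atol=1e-9)


# ---------------------------------------------------------------------------
# delay shift

def test_shift_control_identity_and_lag():
    x = np.arange(100, dtype=float)
    out, window = eng.shift_control(x, 0.0, TR)
    assert window == 100
    np.testing.assert_array_equal(out, x)
    out, window = eng.shift_control(x, 4.0, TR)    # 4 s at TR 2 s = 2 samples
    assert window == 98
    np.testing.assert_array_equal(out, x[2:])
    with pytest.raises(ValueError, match="whole number"):
        eng.shift_control(x, 3.0, TR)


def test_shift_control_round_trip(rng):
    """A control built as the node series delayed by 2 samples realigns
    perfectly under a 4 s shift at TR 2 s."""
    node = rng.standard_normal(200)
    control = np.concatenate([rng.standard_normal(2), node[:-2]])  # 2 samples late
    shifted, window = eng.shift_control(control, 4.0, TR)
    r = np.corrcoef(shifted, node[:window])[0, 1]
    assert r > 0.999999


# ---------------------------------------------------------------------------
# correlation matrices

def test_full_correlation_signs_and_oracle(rng):
    x = rng.standard_normal(100)
    M = eng.full_correlation(np.vstack([x, x, -x])).values
    assert M[0, 1] == pytest.approx(1.0)
    assert M[0, 2] == pytest.approx(-1.0)
    X = rng.standard_normal((5, 200))
    M = eng.full_correlation(X).values
    # brute-force covariance/sd computation
    for i in range(5):
        for j in range(5):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert M[i, j] == pytest.approx(expected, abs=1e-12)


def test_full_correlation_rejects_constant(rng):
    X = rng.standard_normal((3, 50))
    X[1] = 2.5
    with pytest.raises(ValueError, match="constant"):
        eng.full_correlation(X)


def test_partial_correlation_hand_value():
    """r_ij=0.5, r_ix=r_jx=0.5 -> (0.5-0.25)/(1-0.25) = 1/3."""
    M = np.array([[1.0, 0.5], [0.5, 1.0]])
    Mp = eng.partial_from_full(M, np.array([0.5, 0.5]))
    assert Mp[0, 1] == pytest.approx(1.0 / 3.0)


def test_partial_reduces_to_full_when_control_uncorrelated():
    M = np.array([[1.0, 0.3, -0.2], [0.3, 1.0, 0.6], [-0.2, 0.6, 1.0]])
    np.testing.assert_allclose(eng.partial_from_full(M, np.zeros(3)), M, atol=1e-15)


def test_partial_matches_residualization_oracle(rng):
    """Closed form == correlation of control-regressed residuals, to 1e-10,
    on 100 random instances."""
    for _ in range(100):
        X = rng.standard_normal((8, 300))
        c = rng.standard_normal(300)
        Mp = eng.partial_correlation(X, c).values
        cc = np.vstack([np.ones(300), c]).T
        resid = X - (cc @ np.linalg.lstsq(cc, X.T, rcond=None)[0]).T
        oracle = np.corrcoef(resid)
        np.testing.assert_allclose(Mp, oracle, atol=1e-10)


def test_partial_rejects_collinear_control(rng):
    X = rng.standard_normal((3, 80))
    with pytest.raises(ValueError, match="collinear"):
        eng.partial_correlation(X, X[0])


# ---------------------------------------------------------------------------
# G and L metrics

def test_global_metric_examples(rng):
    assert eng.global_metric(np.eye(4)) == 0.0
    M = np.full((90, 90), 0.5)
    np.fill_diagonal(M, 1.0)
    assert eng.global_metric(M) == pytest.approx(2002.5)
    A = rng.standard_normal((6, 6))
    M = (A + A.T) / 2
    brute = sum(M[i, j] for i in range(6) for j in range(i + 1, 6))
    assert eng.global_metric(M) == pytest.approx(brute, abs=1e-12)


def test_local_metric_forms_and_double_counting(rng):
    M = np.full((5, 5), 0.5)
    np.fill_diagonal(M, 1.0)
    assert eng.local_metric(M, 2) == pytest.approx(0.5)            # mean form
    assert eng.local_metric(np.eye(5), 0) == 0.0
    A = rng.standard_normal((7, 7))
    M = (A + A.T) / 2
    np.fill_diagonal(M, 1.0)
    total = eng.local_metrics(M, form="sum").sum()
    assert total == pytest.approx(2 * eng.global_metric(M), abs=1e-10)


# ---------------------------------------------------------------------------
# engagement composition

def _toy_inputs(rng, n_nodes=4, grid=(6, 6, 6), T=120):
    nodes = rng.standard_normal((n_nodes, T))
    vol = rng.standard_normal(grid + (T,))
    mask = np.zeros(grid, bool)
    mask[2:5, 2:5, 2:5] = True
    return nodes, vol, mask


def test_engagement_global_equals_pairwise_reduction_sum(rng):
    nodes, vol, mask = _toy_inputs(rng)
    g, _ = eng.engagement_for_voxel(nodes, vol, mask, (3, 3, 3), 0.0, TR)
    control = eng.neighborhood_average(vol, mask, (3, 3, 3))
    M = eng.full_correlation(nodes).values
    Mp = eng.partial_correlation(nodes, control).values
    iu = np.triu_indices(4, k=1)
    assert g == pytest.approx((M[iu] - Mp[iu]).sum(), abs=1e-12)


def test_engagement_map_matches_per_voxel_calls(rng):
    nodes, vol, mask = _toy_inputs(rng)
    maps = eng.engagement_map(vol, nodes, mask, delays=(0.0, 2.0), tr_seconds=TR)
    for delay in (0.0, 2.0):
        emap = maps[delay]
        assert emap.n_voxels == mask.sum()
        for k in rng.choice(emap.n_voxels, size=5, replace=False):
            voxel = tuple(emap.voxel_index[k])
            g, l = eng.engagement_for_voxel(nodes, vol, mask, voxel, delay, TR)
            assert emap.global_values[k] == pytest.approx(g, abs=1e-9)
            np.testing.assert_allclose(emap.local_values[k], l, atol=1e-9)


def test_engagement_map_restricted_to_mask_and_scale_invariant(rng):
    nodes, vol, mask = _toy_inputs(rng)
    maps = eng.engagement_map(vol, nodes, mask, delays=(0.0,), tr_seconds=TR)
    emap = maps[0.0]
    got = set(map(tuple, emap.voxel_index))
    assert got == set(map(tuple, np.argwhere(mask)))
    # correlation scale invariance: affine rescaling of all inputs
    maps2 = eng.engagement_map(5.0 * vol + 3.0, 2.0 * nodes - 1.0, mask,
                               delays=(0.0,), tr_seconds=TR)
    np.testing.assert_allclose(maps2[0.0].global_values, emap.global_values,
                               atol=1e-9)


def test_engagement_independent_control_shrinks_with_n(rng):
    """A control independent of all nodes engages ~0 for long series."""
    T = 5000
    nodes = rng.standard_normal((5, T))
    vals = []
    for _ in range(20):
        c = rng.standard_normal(T)
        M = eng.full_correlation(nodes).values
        Mp = eng.partial_correlation(nodes, c).values
        vals.append(eng.global_metric(M) - eng.global_metric(Mp))
    # null scale ~ n_pairs / T; the 99% band at this T is tiny
    assert np.abs(vals).max() < 0.05


# ---------------------------------------------------------------------------
# rescaling

def _map_with_values(values):
    from wmengage.types import EngagementMap
    values = np.asarray(values, float)
    mask = np.zeros((6, 6, 6), bool)
    mask.ravel()[: values.size] = True
    return EngagementMap(global_values=values,
                         local_values=np.ones((values.size, 2)), mask=mask,
                         voxel_index=np.argwhere(mask), delay_seconds=0.0)


def test_rescale_percent_examples(rng):
    # hand example {1, 3}: mean 2 -> {-50, +50}
    out = eng.rescale_percent(_map_with_values([1.0, 3.0]))
    np.testing.assert_allclose(out.global_values, [-50.0, 50.0])
    # any valid map rescales to zero mean
    vals = rng.uniform(0.5, 2.0, size=40)
    out = eng.rescale_percent(_map_with_values(vals))
    assert out.global_values.mean() == pytest.approx(0.0, abs=1e-8)
    assert out.rescaled
    # constant map -> all zeros
    out = eng.rescale_percent(_map_with_values(np.full(10, 2.5)))
    np.testing.assert_allclose(out.global_values, 0.0)
    # near-zero mean -> rejected with diagnostic
    with pytest.raises(ValueError, match="mean"):
        eng.rescale_percent(_map_with_values([1.0, -1.0]))
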