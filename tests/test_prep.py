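"""Signal preprocessing: motion expansion, CompCor, regression, filtering,
standardization and fALFF."""

import numpy as np
import pytest

from wmengage import prep

TR = 2.0


# ---------------------------------------------------------------------------
# Friston-24 expansion

def test_friston24_hand_example():
    """Single parameter series (1, 2): squared (1, 4); lagged (0, 1);
    lagged-squared (0, 1)."""
    m = np.zeros((2, 6))
    m[:, 0] = [1.0, 2.0]
    out = prep.friston24_expand(m)
    assert out.shape == (2, 24)
    np.testing.assert_array_equal(out[:, 0], [1, 2])     # R
    np.testing.assert_array_equal(out[:, 6], [0, 1])     # R(t-1)
    np.testing.assert_array_equal(out[:, 12], [1, 4])    # R^2
    np.testing.assert_array_equal(out[:, 18], [0, 1])    # R(t-1)^2


def test_friston24_zero_and_oracle(rng):
    assert not prep.friston24_expand(np.zeros((10, 6))).any()
    R = rng.standard_normal((50, 6))
    out = prep.friston24_expand(R)
    # independent column-by-column expansion
    for j in range(6):
        lag = np.concatenate([[0.0], R[:-1, j]])
        np.testing.assert_allclose(out[:, j], R[:, j])
        np.testing.assert_allclose(out[:, 6 + j], lag)
        np.testing.assert_allclose(out[:, 12 + j], R[:, j] ** 2)
        np.testing.assert_allclose(out[:, 18 + j], lag ** 2)
    with pytest.raises(ValueError, match="6 columns"):
        prep.friston24_expand(R[:, :5])


# ---------------------------------------------------------------------------
# CompCor

def test_compcor_identical_copies(rng):
    base = rng.standard_normal(80)
    roi = np.tile(base, (6, 1)) * rng.uniform(0.5, 2.0, size=(6, 1))
    comp = prep.compcor_components(roi, k=1)
    r = np.corrcoef(comp[:, 0], base)[0, 1]
    assert abs(r) > 0.999999


def test_compcor_orthogonality_and_scaling(rng):
    comp = prep.compcor_components(rng.standard_normal((20, 100)), k=5)
    gram = comp.T @ comp
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
    np.testing.assert_allclose(comp.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_compcor_recovers_known_basis(rng):
    """ROI mixed from 3 orthogonal sources: top-3 components span them."""
    g = rng.standard_normal((120, 3))
    g -= g.mean(axis=0)                        # CompCor demeans each series
    q, _ = np.linalg.qr(g)
    sources = q.T                              # 3 orthonormal zero-mean series
    mixing = rng.standard_normal((20, 3))
    roi = mixing @ sources
    comp = prep.compcor_components(roi, k=3)
    # principal angles between span(comp) and span(sources)
    qc, _ = np.linalg.qr(comp)
    qs, _ = np.linalg.qr(sources.T)
    sv = np.linalg.svd(qc.T @ qs, compute_uv=False)
    assert np.all(np.arccos(np.clip(sv, -1, 1)) < 1e-6)
    with pytest.raises(ValueError, match="rank"):
        prep.compcor_components(roi, k=10)


# ---------------------------------------------------------------------------
# confound regression

def test_regress_confounds_identity_and_orthogonal(rng):
    c = rng.standard_normal(60)
    out = prep.regress_confounds(c[None, :], c[:, None])
    np.testing.assert_allclose(out, 0.0, atol=1e-10)
    # target orthogonal to the whole design (intercept + confound):
    # returned unchanged
    X = np.vstack([np.ones(60), c]).T
    x = np.sin(np.arange(60))
    x -= X @ np.linalg.lstsq(X, x, rcond=None)[0]
    out = prep.regress_confounds(x[None, :], c[:, None])
    np.testing.assert_allclose(out[0], x, atol=1e-8)


def test_regress_confounds_matches_normal_equations(rng):
    Y = rng.standard_normal((7, 90))
    C = rng.standard_normal((90, 4))
    out = prep.regress_confounds(Y, C)
    X = np.hstack([np.ones((90, 1)), C])
    beta = np.linalg.solve(X.T @ X, X.T @ Y.T)
    np.testing.assert_allclose(out, Y - (X @ beta).T, atol=1e-8)
    # residuals orthogonal to every confound column
    assert np.abs(out @ X).max() < 1e-8


def test_regress_confounds_drops_collinear(rng):
    C = rng.standard_normal((50, 2))
    C = np.hstack([C, C[:, :1] * 2.0])
    with pytest.warns(UserWarning, match="collinear"):
        out = prep.regress_confounds(rng.standard_normal((3, 50)), C)
    assert out.shape == (3, 50)


# ---------------------------------------------------------------------------
# filtering

def _sine(freq_hz, n=600, tr=TR):
    return np.sin(2 * np.pi * freq_hz * np.arange(n) * tr)


MID = slice(100, 500)                          # ignore filter edge transients


def test_bandpass_preserves_band_center():
    x = _sine(0.05)
    y = prep.bandpass(x, TR)[0]
    ratio = np.abs(y[MID]).max() / np.abs(x[MID]).max()
    assert abs(ratio - 1.0) < 0.05
    # zero phase: the filtered tone is in phase with the input
    xc, yc = x[MID], y[MID]
    cos_phase = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    assert cos_phase > 0.999


def test_bandpass_attenuates_out_of_band():
    x = _sine(0.2)
    y = prep.bandpass(x, TR)[0]
    assert np.sqrt((y[MID] ** 2).mean()) < 0.10 * np.sqrt((x[MID] ** 2).mean())


def test_detrend_kills_ramp():
    ramp = np.linspace(0.0, 7.0, 150)
    out = prep.detrend(ramp)[0]
    assert np.abs(out).max() < 1e-6 * 7.0


def test_filter_linearity(rng):
    x, y = rng.standard_normal((2, 180))
    lhs = prep.bandpass(3.0 * x - 0.5 * y, TR)
    rhs = 3.0 * prep.bandpass(x, TR) - 0.5 * prep.bandpass(y, TR)
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_bandpass_rejects_bad_band():
    with pytest.raises(ValueError, match="Nyquist"):
        prep.bandpass(np.zeros(100), TR, low_hz=0.01, high_hz=0.3)


# ---------------------------------------------------------------------------
# standardization

def test_standardize_hand_example_and_idempotence(rng):
    out = prep.standardize(np.array([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out[0], [-1.0, 0.0, 1.0])   # sd with n-1 divisor
    z = prep.standardize(rng.standard_normal((4, 100)))
    np.testing.assert_allclose(prep.standardize(z), z, atol=1e-10)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(z.var(axis=1, ddof=1), 1.0, atol=1e-10)
    with pytest.raises(ValueError, match="constant"):
        prep.standardize(np.ones((1, 10)))


# ---------------------------------------------------------------------------
# fALFF

def test_falff_sinusoids():
    assert prep.compute_falff(_sine(0.05, n=256), TR) > 0.95
    assert prep.compute_falff(_sine(0.2, n=256), TR) < 0.05
    # leakage-free check at an exact DFT bin frequency
    exact = np.sin(2 * np.pi * (26 / 512) * np.arange(256) * TR)
    assert prep.compute_falff(exact, TR) > 0.999


def test_falff_white_noise_matches_bin_counting(rng):
    """Mean fALFF of white noise ~ in-band fraction of positive DFT bins."""
    X = rng.standard_normal((1000, 256))
    vals = prep.compute_falff(X, TR)
    freqs = np.fft.rfftfreq(256, d=TR)
    pos = freqs > 0
    band = pos & (freqs >= 0.01) & (freqs <= 0.1)
    expected = band.sum() / pos.sum()
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - expected) < 3 * se


def test_falff_scale_invariance_and_errors(rng):
    x = rng.standard_normal(128)
    a = prep.compute_falff(x, TR)
    b = prep.compute_falff(17.5 * x, TR)
    assert a == pytest.approx(b, abs=1e-12)
    with pytest.raises(ValueError, match="64"):
        prep.compute_falff(x[:32], TR)
    with pytest.raises(ValueError, match="zero total power"):
        prep.compute_falff(np.ones(128), TR)


# ---------------------------------------------------------------------------
# orchestration

def test_preprocess_subject_order_and_outputs(rng):
    series = rng.standard_normal((12, 150)) + np.linspace(0, 3, 150)
    motion = np.cumsum(0.01 * rng.standard_normal((150, 6)), axis=0)
    csf = rng.standard_normal((8, 150))
    clean, falff, prov = prep.preprocess_subject(series, TR, motion6=motion,
                                                 compcor_ts=csf, compcor_k=3)
    assert clean.shape == series.shape
    np.testing.assert_allclose(clean.mean(axis=1), 0.0, atol=1e-8)
    np.testing.assert_allclose(clean.var(axis=1, ddof=1), 1.0, atol=1e-6)
    assert falff.shape == (12,) and np.all((falff >= 0) & (falff <= 1))
    order = [s["stage"] for s in prov["stages"]]
    assert order == ["motion_regression", "compcor_regression", "drift_correction",
                     "falff_snapshot", "bandpass", "standardize"]
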