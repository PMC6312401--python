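"""Sign-flip permutation machinery, cluster correction, ERP peaks, paired t."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from oriem import cluster_test, erp_peak_components, paired_t, sign_flip_null
from oriem.stats import _group_t


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_identical_samples():
    t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0 and df == 2


def test_paired_t_textbook_example():
    # diffs -1, -2, -3: mean -2, sd 1 -> t = -2 / (1/sqrt(3)) = -3.4641
    t, df, p = paired_t([1, 2, 3], [2, 4, 6])
    assert t == pytest.approx(-3.4641016, abs=1e-6)
    assert df == 2


def test_paired_t_degrees_of_freedom_and_errors():
    t, df, p = paired_t([1.0, 3.0], [0.0, 1.0])
    assert df == 1
    with pytest.raises(ValueError, match="zero variance"):
        paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="n >= 2"):
        paired_t([1.0], [2.0])


# ---------------------------------------------------------------------------
# sign-flip null
# ---------------------------------------------------------------------------

def test_sign_flip_null_zero_data():
    null = sign_flip_null(np.zeros((4, 20)), n_perm=200, seed=0)
    assert np.all(null == 0)


def test_sign_flip_null_deterministic():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 30))
    a = sign_flip_null(data, n_perm=300, seed=5)
    b = sign_flip_null(data, n_perm=300, seed=5)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, sign_flip_null(data, n_perm=300, seed=6))


def test_sign_flip_null_mean_symmetric_around_zero():
    rng = np.random.default_rng(1)
    data = rng.normal(1.0, 1.0, size=(8, 40))
    null = sign_flip_null(data, n_perm=2000, seed=0, statistic="mean")
    assert abs(null.mean()) < 3 * null.std() / np.sqrt(null.size / 40)


def test_sign_flip_warns_on_low_n_perm():
    with pytest.warns(UserWarning, match="low"):
        sign_flip_null(np.random.default_rng(0).normal(size=(4, 5)), n_perm=50, seed=0)


def test_null_quantile_of_h0_statistic_is_uniform():
    """Exchangeability under H0: the observed max |t| falls at a uniform
    quantile of its sign-flip null (Kolmogorov-Smirnov over 200 simulations)."""
    rng = np.random.default_rng(7)
    quantiles = []
    for _ in range(200):
        data = rng.normal(size=(10, 25))
        null = sign_flip_null(data, n_perm=200, seed=int(rng.integers(1 << 30)))
        obs = np.abs(_group_t(data)).max()
        null_max = np.abs(null).max(axis=1)
        quantiles.append((null_max < obs).mean())
    _, p = sp_stats.kstest(quantiles, "uniform")
    assert p > 0.01


# ---------------------------------------------------------------------------
# cluster test
# ---------------------------------------------------------------------------

def _effect_data(rng, n_sub=12, T=50, window=slice(20, 32), amp=1.5):
    data = rng.normal(size=(n_sub, T))
    data[:, window] += amp
    return data


def test_single_suprathreshold_point_cluster():
    rng = np.random.default_rng(2)
    data = rng.normal(0, 0.1, size=(8, 30))
    data[:, 15] += 5.0
    res = cluster_test(data, n_perm=500, seed=0)
    assert len(res.clusters) >= 1
    top = res.clusters[0]
    assert list(top.indices) == [15]
    assert top.mass == pytest.approx(_group_t(data)[15])
    assert top.p_value < 0.05


def test_cluster_recovers_injected_window():
    rng = np.random.default_rng(3)
    data = _effect_data(rng)
    res = cluster_test(data, n_perm=1000, seed=0)
    sig = [c for c in res.clusters if c.p_value < 0.05]
    assert sig
    covered = set(sig[0].indices)
    assert len(covered & set(range(20, 32))) >= 0.8 * 12


def test_cluster_empty_result_is_valid():
    data = np.random.default_rng(4).normal(0, 1e-3, size=(6, 20))
    res = cluster_test(data + 0, n_perm=200, seed=0)
    assert isinstance(res.clusters, list)
    d = res.to_dict()
    assert d["n_permutations"] == 200


def test_cluster_p_values_never_zero():
    rng = np.random.default_rng(5)
    data = _effect_data(rng, amp=5.0)
    res = cluster_test(data, n_perm=200, seed=0)
    for c in res.clusters:
        assert c.p_value >= 1 / 201


def test_cluster_2d_four_connectivity():
    rng = np.random.default_rng(6)
    data = rng.normal(size=(10, 12, 12))
    data[:, 3:7, 3:7] += 2.0
    res = cluster_test(data, n_perm=300, seed=0)
    assert res.observed_stat.shape == (12, 12)
    sig = [c for c in res.clusters if c.p_value < 0.05]
    assert sig
    coords = {tuple(c) for c in sig[0].indices}
    assert {(4, 4), (5, 5)} <= coords


def test_cluster_matches_mne_oracle():
    """Observed clusters and corrected p-values agree with mne's
    implementation of the same 1-sample cluster permutation test."""
    from mne.stats import permutation_cluster_1samp_test

    rng = np.random.default_rng(8)
    data = _effect_data(rng, n_sub=14, amp=1.2)
    df = data.shape[0] - 1
    thr = sp_stats.t.ppf(1 - 0.025, df)
    res = cluster_test(data, n_perm=2000, seed=0)
    t_obs, clusters, pvals, _ = permutation_cluster_1samp_test(
        data, threshold=thr, n_permutations=2000, tail=0, stat_fun=None,
        seed=1, out_type="indices", verbose=False)
    np.testing.assert_allclose(res.observed_stat, t_obs, atol=1e-8)
    ours = sorted([tuple(np.sort(c.indices)) for c in res.clusters])
    theirs = sorted([tuple(np.sort(c[0])) for c in clusters])
    assert ours == theirs
    our_best = min(c.p_value for c in res.clusters)
    their_best = float(np.min(pvals))
    assert abs(our_best - their_best) < 0.05


def test_invalid_inputs():
    with pytest.raises(ValueError, match="subjects"):
        sign_flip_null(np.zeros((1, 5)), n_perm=100)
    with pytest.raises(ValueError, match="tail"):
        cluster_test(np.zeros((4, 5)), n_perm=100, tail="sideways")


# ---------------------------------------------------------------------------
# ERP components
# ---------------------------------------------------------------------------

def _bump(times, center, width=0.01, amp=1.0):
    return amp * np.exp(-((times - center) ** 2) / (2 * width**2))


def test_p1_peak_on_synthetic_bump():
    times = np.arange(-0.1, 0.4, 1 / 256)
    trace = _bump(times, 0.095)
    comps = erp_peak_components(trace, times)
    assert comps["p1_latency_ms"].iloc[0] == pytest.approx(95.0, abs=4.0)
    assert comps["p1_amplitude"].iloc[0] == pytest.approx(1.0, abs=0.01)
    # N1 = largest negativity: for a positive bump it sits at a window edge
    n1_lat = comps["n1_latency_ms"].iloc[0]
    assert n1_lat == pytest.approx(130.0, abs=4.0) or n1_lat == pytest.approx(90.0, abs=4.0)


def test_amplitude_scaling_is_linear():
    times = np.arange(-0.1, 0.4, 1 / 256)
    base = _bump(times, 0.095)
    comps = erp_peak_components(np.vstack([base, 2 * base]), times)
    assert comps["p1_amplitude"].iloc[1] == pytest.approx(
        2 * comps["p1_amplitude"].iloc[0])


def test_tied_peaks_take_earliest():
    times = np.arange(-0.1, 0.4, 1 / 256)
    trace = np.zeros_like(times)
    window = (times >= 0.08) & (times <= 0.11)
    idx = np.flatnonzero(window)
    trace[idx[2]] = trace[idx[5]] = 3.0
    comps = erp_peak_components(trace, times)
    assert comps["p1_latency_ms"].iloc[0] == pytest.approx(times[idx[2]] * 1000, abs=1e-6)


def test_window_outside_trace_rejected():
    times = np.arange(0.0, 0.05, 1 / 256)
    with pytest.raises(ValueError, match="outside"):
        erp_peak_components(np.zeros_like(times), times)
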