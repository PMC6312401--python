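"""Forward encoding model: basis, weight estimation, inversion, CV, centering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oriem import (
    CONDITIONS,
    ForwardEncoder,
    build_design_matrix,
    center_responses,
    cross_temporal_generalise,
    encode_timecourse,
    fit_weights,
    invert_model,
    make_basis,
)
from oriem.design import ExperimentDesign, generate_session_design
from oriem.encoding import RankDeficientError
from oriem.simulate import injected_profile, simulate_epochs

from conftest import make_config


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

def test_basis_peak_and_null():
    b = make_basis()
    act = b.evaluate(40.0)
    assert act[2] == pytest.approx(1.0)               # channel at 40 deg
    assert act[1] == pytest.approx(0.6080, abs=2e-4)  # channel at 20 deg
    # 90-degree orientation distance is an exact null: 130 deg vs 40-deg channel
    assert b.evaluate(130.0)[2] == pytest.approx(0.0, abs=1e-12)


def test_basis_periodicity_and_channel_sum():
    b = make_basis()
    grid = np.arange(0, 180, 0.1)
    act = b.evaluate(grid)
    np.testing.assert_allclose(act.sum(axis=0), 315 / 128, atol=1e-10)
    np.testing.assert_allclose(b.evaluate(grid + 180.0), act, atol=1e-12)


def test_basis_validation():
    with pytest.raises(ValueError, match="even"):
        make_basis(exponent=7)
    with pytest.raises(ValueError, match="channels"):
        make_basis(n_channels=1)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(n_channels=st.integers(5, 12), exponent=st.sampled_from([2, 4, 6, 8]))
def test_channel_sum_constant_for_any_valid_basis(n_channels, exponent):
    # harmonic cancellation requires more channels than exponent/2
    b = make_basis(n_channels, exponent)
    theta = np.linspace(0, 180, 91)
    sums = b.evaluate(theta).sum(axis=0)
    if n_channels > exponent // 2:
        np.testing.assert_allclose(sums, b.channel_sum, atol=1e-10)


def test_design_matrix_full_rank_on_grid():
    b = make_basis()
    C = build_design_matrix(np.arange(0, 180, 20), b)
    assert C.shape == (9, 9)
    assert np.linalg.matrix_rank(C) == 9
    # duplicate orientations give duplicate columns
    C2 = build_design_matrix([40.0, 40.0], b)
    np.testing.assert_array_equal(C2[:, 0], C2[:, 1])
    with pytest.raises(ValueError, match="empty"):
        build_design_matrix([], b)


# ---------------------------------------------------------------------------
# weights and inversion vs independent oracles
# ---------------------------------------------------------------------------

def test_fit_weights_noiseless_identifiability():
    rng = np.random.default_rng(0)
    b = make_basis()
    W0 = rng.normal(size=(16, 9))
    ori = np.tile(np.arange(0, 180, 20), 4)
    C = build_design_matrix(ori, b)
    W = fit_weights(W0 @ C, C)
    assert np.abs(W - W0).max() < 1e-8


def test_fit_weights_matches_normal_equations_oracle():
    rng = np.random.default_rng(1)
    B = rng.normal(size=(2, 3))
    C = rng.normal(size=(2, 3))
    # independent oracle: explicit normal equations with matrix inverse
    W_oracle = B @ C.T @ np.linalg.inv(C @ C.T)
    np.testing.assert_allclose(fit_weights(B, C), W_oracle, atol=1e-10)


def test_fit_weights_underdetermined():
    rng = np.random.default_rng(2)
    C = build_design_matrix(np.arange(0, 160, 20), make_basis())  # 8 trials
    with pytest.raises(RankDeficientError, match="8 training trials"):
        fit_weights(rng.normal(size=(4, 8)), C)
    # rank-deficient square case reports the condition number
    Cdup = build_design_matrix([0.0] * 12, make_basis())
    with pytest.raises(RankDeficientError, match="condition number"):
        fit_weights(rng.normal(size=(4, 12)), Cdup)


def test_invert_model_round_trip_and_oracle():
    rng = np.random.default_rng(3)
    W = rng.normal(size=(16, 9))
    c = rng.normal(size=9)
    rec = invert_model(W, (W @ c)[:, None])
    np.testing.assert_allclose(rec[:, 0], c, atol=1e-8)
    assert np.all(invert_model(W, np.zeros((16, 2))) == 0)
    B = rng.normal(size=(16, 5))
    np.testing.assert_allclose(invert_model(W, B), np.linalg.pinv(W) @ B, atol=1e-10)
    with pytest.raises(RankDeficientError):
        invert_model(np.ones((16, 9)), B)


def test_forward_encoder_sklearn_contract():
    from sklearn.base import clone

    rng = np.random.default_rng(4)
    ori = np.tile(np.arange(0, 180, 20), 5)
    W0 = rng.normal(size=(12, 9))
    X = (W0 @ build_design_matrix(ori, make_basis())).T
    enc = ForwardEncoder()
    assert clone(enc).get_params()["exponent"] == 8
    enc.fit(X, ori)
    assert enc.weights_.shape == (12, 9)
    rec = enc.transform(X)
    np.testing.assert_allclose(rec, build_design_matrix(ori, enc.basis_).T, atol=1e-8)


# ---------------------------------------------------------------------------
# sliding-window cross-validated reconstruction
# ---------------------------------------------------------------------------

def test_noiseless_round_trip_recovers_injected_profile(noiseless_epochs):
    epochs, _ = noiseless_epochs
    tensor = center_responses(encode_timecourse(epochs, tmin=0.72, tmax=0.85))
    prof = injected_profile(tensor.basis, make_config())
    mean = tensor.responses.mean(axis=(0, 2))
    np.testing.assert_allclose(mean, prof, atol=1e-6)


def test_responses_near_zero_outside_signal_window(noiseless_epochs):
    epochs, _ = noiseless_epochs
    tensor = encode_timecourse(epochs, tmin=0.3, tmax=0.6)
    assert np.abs(tensor.responses).max() < 1e-8


def test_loo_and_kfold_agree_in_noiseless_limit(noiseless_epochs):
    epochs, _ = noiseless_epochs
    a = encode_timecourse(epochs, tmin=0.73, tmax=0.8, cv="loo")
    b = encode_timecourse(epochs, tmin=0.73, tmax=0.8, cv="kfold10")
    np.testing.assert_allclose(a.responses, b.responses, atol=1e-6)


def test_shuffled_orientations_destroy_selectivity():
    design = generate_session_design(6, 135, seed=17)
    cfg = make_config(n_blocks=6, trials_per_block=135, seed=17,
                      tuning_gain_by_condition={c: 1.0 for c in CONDITIONS})
    epochs, _ = simulate_epochs(design, cfg)

    def contrast(ep):
        tensor = center_responses(encode_timecourse(ep, tmin=0.73, tmax=0.8))
        mean = tensor.responses.mean(axis=(0, 2))
        return mean[4] - mean[[0, -1]].mean()

    intact = contrast(epochs)
    rng = np.random.default_rng(0)
    table = design.table.copy()
    shuffled = table["orientation_second"].to_numpy().copy()
    rng.shuffle(shuffled)
    table["orientation_second"] = shuffled
    table["orientation_first"] = shuffled  # keep trial-type invariant
    broken_design = ExperimentDesign(table=table, n_blocks=6, trials_per_block=135)
    broken = epochs.copy_with(design=broken_design)
    assert intact > 0.5
    assert abs(contrast(broken)) < intact / 3


def test_fold_hygiene_no_trial_trains_its_own_weights(small_design):
    from oriem.encoding import _make_folds

    folds = _make_folds(small_design.table, "kfold10", seed=0)
    seen = np.zeros(len(small_design), dtype=int)
    for train, test in folds:
        assert len(np.intersect1d(train, test)) == 0
        seen[test] += 1
    assert np.all(seen == 1)


def test_rejected_trials_excluded(noiseless_epochs):
    epochs, _ = noiseless_epochs
    mask = np.zeros(epochs.n_trials, dtype=bool)
    mask[:10] = True
    tensor = encode_timecourse(epochs.copy_with(rejected_mask=mask), tmin=0.73, tmax=0.8)
    assert tensor.responses.shape[0] == epochs.n_trials - 10
    assert len(tensor.design) == epochs.n_trials - 10


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def test_centering_moves_peak_to_zero_offset(noiseless_epochs):
    epochs, _ = noiseless_epochs
    tensor = encode_timecourse(epochs, tmin=0.73, tmax=0.8)
    cen = center_responses(tensor)
    assert cen.channel_offsets[4] == 0.0
    peaks = cen.responses.mean(axis=2).argmax(axis=1)
    assert np.all(peaks == 4)
    with pytest.raises(ValueError, match="already centered"):
        center_responses(cen)


def test_centering_shift_enumeration_and_sum_conservation(noiseless_epochs):
    epochs, _ = noiseless_epochs
    tensor = encode_timecourse(epochs, tmin=0.73, tmax=0.8)
    cen = center_responses(tensor)
    # channel-sum is invariant under the per-trial circular shift
    np.testing.assert_allclose(cen.responses.sum(axis=1), tensor.responses.sum(axis=1),
                               atol=1e-9)
    # all 9 cyclic rotations occur across the 9 presented orientations
    ori = tensor.design["orientation_second"].to_numpy()
    shifts = {(4 - o // 20) % 9 for o in ori}
    assert shifts == set(range(9))


def test_equivariance_under_grid_rotation(small_design):
    cfg = make_config(noise_sd_uV=0.0, pink_noise_sd_uV=0.0,
                      tuning_gain_by_condition={c: 1.0 for c in CONDITIONS})
    epochs, _ = simulate_epochs(small_design, cfg)
    table = small_design.table.copy()
    table["orientation_second"] = (table["orientation_second"] + 20) % 180
    table["orientation_first"] = (table["orientation_first"] + 20) % 180
    rotated_design = ExperimentDesign(table=table, n_blocks=2, trials_per_block=45)
    rotated, _ = simulate_epochs(rotated_design, cfg)
    base_mean = encode_timecourse(epochs, tmin=0.73, tmax=0.8).responses.mean(axis=0)
    rot_mean = encode_timecourse(rotated, tmin=0.73, tmax=0.8).responses.mean(axis=0)
    np.testing.assert_allclose(np.roll(base_mean, 1, axis=0), rot_mean, atol=1e-9)


# ---------------------------------------------------------------------------
# cross-temporal generalisation
# ---------------------------------------------------------------------------

def test_generalisation_square_block_for_stable_topography(small_design):
    cfg = make_config(noise_sd_uV=0.05, pink_noise_sd_uV=0.0,
                      tuning_gain_by_condition={c: 1.0 for c in CONDITIONS})
    epochs, _ = simulate_epochs(small_design, cfg)
    gmap = cross_temporal_generalise(epochs, tmin=0.5, tmax=1.1, step_ms=16)
    t = gmap.train_times
    inside = (t > 0.73) & (t < 0.84)
    outside = t < 0.63
    S = gmap.selectivity
    assert S[np.ix_(inside, inside)].mean() > 0.9
    assert abs(S[np.ix_(inside, outside)].mean()) < 0.05
    assert abs(S[np.ix_(outside, outside)].mean()) < 0.05


def test_generalisation_diagonal_matches_timecourse(small_design):
    cfg = make_config(noise_sd_uV=0.05, pink_noise_sd_uV=0.0,
                      tuning_gain_by_condition={c: 1.0 for c in CONDITIONS})
    epochs, _ = simulate_epochs(small_design, cfg)
    gmap = cross_temporal_generalise(epochs, tmin=0.7, tmax=0.9, step_ms=16)
    tensor = center_responses(encode_timecourse(epochs, tmin=0.7, tmax=0.9, step_ms=16))
    mean = tensor.responses.mean(axis=0)
    contrast = mean[4] - mean[[0, 8]].mean(axis=0)
    np.testing.assert_allclose(np.diag(gmap.selectivity), contrast, atol=1e-9)


def test_response_container_round_trip(tmp_path, noiseless_epochs):
    from oriem.encoding import read_responses, write_responses

    epochs, _ = noiseless_epochs
    tensor = center_responses(encode_timecourse(epochs, tmin=0.73, tmax=0.8))
    path = write_responses(tensor, tmp_path / "resp")
    back = read_responses(path)
    np.testing.assert_array_equal(back.responses,
                                  tensor.responses.astype(np.float32))
    assert back.centered and list(back.channel_offsets) == list(tensor.channel_offsets)
    np.testing.assert_allclose(back.time_axis, tensor.time_axis)
    assert back.design["orientation_second"].tolist() == \
        tensor.design["orientation_second"].tolist()


def test_generalisation_csv_export(tmp_path, small_design):
    cfg = make_config(noise_sd_uV=0.1, pink_noise_sd_uV=0.0)
    epochs, _ = simulate_epochs(small_design, cfg)
    gmap = cross_temporal_generalise(epochs, tmin=0.7, tmax=0.8, step_ms=16)
    path = gmap.to_csv(tmp_path / "gmap.csv")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("# train_times_s:")
    loaded = np.loadtxt([l for l in lines if not l.startswith("#")], delimiter=",")
    np.testing.assert_allclose(loaded, gmap.selectivity, rtol=1e-6)
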