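"""EEG decoding: pseudotrials, the SVM backend, timecourses, generalization."""

import numpy as np
import pytest
from sklearn.svm import SVC

import imfusion as im
from imfusion import _svm
from imfusion.decoding import aggregate_pairs, make_pseudotrials

from conftest import epochs_from_array, small_truth


def _noise_epochs(rng, n_cond=4, trials_per=12, n_ch=8, n_t=30):
    conds = np.repeat(np.arange(1, n_cond + 1), trials_per)
    data = rng.standard_normal((len(conds), n_ch, n_t))
    return epochs_from_array(data, conds)


# ---------------------------------------------------------------- pseudotrials


def test_pseudotrial_floor_division_drops_leftovers():
    rng = np.random.default_rng(0)
    conds = np.repeat([1, 2], 23)
    ep = epochs_from_array(rng.standard_normal((46, 3, 5)), conds, n_people=1)
    ps = make_pseudotrials(ep, chunk_size=5, seed=1)
    assert ps.data.shape[:2] == (2, 4)  # floor(23/5) = 4, 3 trials dropped
    assert all(len(ch) == 5 for cond in ps.chunks for ch in cond)


def test_pseudotrial_of_identical_trials_equals_the_trial():
    base = np.arange(3 * 4, dtype=float).reshape(1, 3, 4)
    data = np.repeat(base, 10, axis=0)
    ep = epochs_from_array(data, np.repeat([1, 2], 5), n_people=1)
    ps = make_pseudotrials(ep, chunk_size=5, seed=0)
    assert np.allclose(ps.data[0, 0], base[0])


def test_pseudotrial_means_match_stored_chunk_assignment():
    """Brute-force recomputation of means from the recorded chunks."""
    rng = np.random.default_rng(7)
    ep = _noise_epochs(rng, n_cond=2, trials_per=13, n_ch=2, n_t=3)
    ps = make_pseudotrials(ep, chunk_size=5, seed=3)
    for ci in range(2):
        for pi, chunk in enumerate(ps.chunks[ci]):
            assert np.allclose(ps.data[ci, pi], ep.data[chunk].mean(axis=0))


def test_pseudotrials_require_enough_trials():
    rng = np.random.default_rng(1)
    ep = _noise_epochs(rng, n_cond=2, trials_per=4)
    with pytest.raises(ValueError):
        make_pseudotrials(ep, chunk_size=5)
    # one pseudotrial per condition is constructible but not decodable
    ep8 = _noise_epochs(rng, n_cond=2, trials_per=8)
    assert make_pseudotrials(ep8, chunk_size=5).data.shape[1] == 1
    with pytest.raises(ValueError):
        im.decode_timecourse(ep8, chunk_size=5, n_iter=1, seed=0)


# ------------------------------------------------------------------- backend


def test_smo_matches_libsvm_decision_values():
    """The numba SMO solver must agree with libsvm on random problems."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        n, f = 14, 20
        x = rng.standard_normal((n, f))
        y = np.r_[np.ones(7), -np.ones(7)]
        x[y > 0] += rng.uniform(0, 1.5)  # varying separability
        xt = rng.standard_normal((10, f))
        beta, b = _svm.smo_train(x @ x.T, y, 1.0, 1e-4, 100_000)
        dv = xt @ (x.T @ beta) + b
        ref = SVC(kernel="linear", C=1.0, tol=1e-4).fit(x, y).decision_function(xt)
        assert np.allclose(dv, ref, atol=1e-2, rtol=1e-2)
        agree = np.sign(dv[np.abs(dv) > 1e-6]) == np.sign(ref[np.abs(dv) > 1e-6])
        assert agree.all()


# ----------------------------------------------------------------- timecourse


def test_separable_conditions_decode_perfectly():
    """Disjoint constant patterns with no noise give 100% at every time."""
    n_per = 10
    data = np.zeros((2 * n_per, 4, 12))
    data[:n_per, 0, :] = 1.0  # condition 1 lives on channel 0
    data[n_per:, 1, :] = 1.0  # condition 2 on channel 1
    ep = epochs_from_array(data, np.repeat([1, 2], n_per), n_people=1)
    res = im.decode_timecourse(ep, window=3, chunk_size=5, n_iter=2, seed=0)
    assert res.accuracy.shape[0] == 1
    assert np.allclose(res.accuracy, 100.0)


def test_noise_data_decodes_at_chance():
    rng = np.random.default_rng(5)
    ep = _noise_epochs(rng, n_cond=4, trials_per=12, n_ch=8, n_t=40)
    res = im.decode_timecourse(ep, window=3, chunk_size=4, n_iter=3, seed=2)
    assert 45.0 < res.accuracy.mean() < 55.0


def test_planted_category_window_bounds_above_chance_region():
    """Across-category decoding exceeds chance only inside the window."""
    truth = small_truth(category_effect_eeg=0.4, rois={},
                        category_latency_ms=(400.0, 900.0))
    design = im.make_design(2, 10, 12, seed=1)
    ep = im.generate_eeg(design, truth, seed=2)
    res = im.decode_timecourse(ep, window=3, chunk_size=5, n_iter=3, seed=3)
    cat = aggregate_pairs(res, "category")
    inside = (cat.time_ms > 500) & (cat.time_ms < 800)
    before = cat.time_ms < 300
    assert cat.accuracy[inside].mean() > 65.0
    assert 45.0 < cat.accuracy[before].mean() < 55.0
    # within-category pairs carry no signal here (wide band: few trials)
    wp = aggregate_pairs(res, "within_people")
    assert 40.0 < wp.accuracy[inside].mean() < 60.0


def test_decode_accuracy_time_grid_truncates_window_edges():
    rng = np.random.default_rng(3)
    ep = _noise_epochs(rng, n_cond=2, trials_per=8, n_ch=3, n_t=20)
    res = im.decode_timecourse(ep, window=5, chunk_size=4, n_iter=1, seed=0)
    assert len(res.time_ms) == 20 - 4
    assert res.time_ms[0] == ep.time_ms[2]


def test_decode_determinism_per_seed():
    rng = np.random.default_rng(4)
    ep = _noise_epochs(rng, n_cond=2, trials_per=10, n_ch=4, n_t=15)
    a = im.decode_timecourse(ep, chunk_size=5, n_iter=2, seed=7)
    b = im.decode_timecourse(ep, chunk_size=5, n_iter=2, seed=7)
    c = im.decode_timecourse(ep, chunk_size=5, n_iter=2, seed=8)
    assert np.array_equal(a.accuracy, b.accuracy)
    assert not np.array_equal(a.accuracy, c.accuracy)


def test_iteration_averaging_reduces_across_seed_variance():
    rng = np.random.default_rng(9)
    ep = _noise_epochs(rng, n_cond=2, trials_per=12, n_ch=4, n_t=10)
    one, many = [], []
    for s in range(6):
        one.append(im.decode_timecourse(ep, chunk_size=4, n_iter=1, seed=s).accuracy.mean())
        many.append(im.decode_timecourse(ep, chunk_size=4, n_iter=8, seed=s).accuracy.mean())
    assert np.std(many) < np.std(one)


# --------------------------------------------------------------- aggregation


def test_pair_bookkeeping_and_aggregate_means():
    rng = np.random.default_rng(0)
    ep = _noise_epochs(rng, n_cond=12, trials_per=4, n_ch=3, n_t=4)
    res = im.decode_timecourse(ep, window=1, chunk_size=2, n_iter=1, seed=0)
    kinds = res.pairs["kind"].value_counts()
    assert len(res.pairs) == 66
    assert kinds["across"] == 36 and kinds["within_people"] == 15 and kinds["within_places"] == 15
    for mode in ("category", "within_people", "within_places"):
        agg = aggregate_pairs(res, mode)
        mask = (res.pairs["kind"] == {"category": "across"}.get(mode, mode)).to_numpy()
        assert np.allclose(agg.accuracy, res.accuracy[mask].mean(axis=0))


def test_aggregate_constant_pairs_is_constant():
    res = im.decoding.DecodingTimeseries(
        time_ms=np.arange(5.0),
        accuracy=np.full((66, 5), 50.0),
        level="per_pair",
        n_iterations=1,
        pairs=im.pair_table(),
    )
    for mode in ("category", "within_people", "within_places"):
        assert np.allclose(aggregate_pairs(res, mode).accuracy, 50.0)


def test_aggregate_rejects_incomplete_pairs():
    res = im.decoding.DecodingTimeseries(
        time_ms=np.arange(5.0),
        accuracy=np.full((65, 5), 50.0),
        level="per_pair",
        n_iterations=1,
        pairs=im.pair_table().iloc[:65],
    )
    with pytest.raises(ValueError):
        aggregate_pairs(res, "category")


# ------------------------------------------------------------ generalization


def test_timegen_null_is_flat_at_chance():
    rng = np.random.default_rng(2)
    ep = _noise_epochs(rng, n_cond=4, trials_per=12, n_ch=6, n_t=24)
    tg = im.time_generalize(ep, n_iter=4, seed=1)
    assert 45.0 < tg.accuracy.mean() < 55.0


def test_timegen_stationary_signal_generalizes_everywhere():
    """A temporally constant category signal fills the whole matrix."""
    rng = np.random.default_rng(3)
    n_per, n_ch, n_t = 12, 6, 20
    conds = np.repeat(np.arange(1, 5), n_per)
    data = rng.standard_normal((len(conds), n_ch, n_t)) * 0.3
    sign = np.where(conds <= 2, 1.0, -1.0)
    data[:, 0, :] += sign[:, None]  # constant category channel
    ep = epochs_from_array(data, conds)
    tg = im.time_generalize(ep, n_iter=4, seed=0)
    assert tg.accuracy.min() > 75.0


def test_timegen_diagonal_tracks_category_timecourse():
    """The matrix diagonal and the category curve rise and fall together."""
    truth = small_truth(category_effect_eeg=0.5, rois={},
                        category_latency_ms=(300.0, 800.0))
    design = im.make_design(2, 10, 12, seed=4)
    ep = im.generate_eeg(design, truth, seed=5)
    tg = im.time_generalize(ep, n_iter=3, seed=6, time_step=4)
    cat = aggregate_pairs(
        im.decode_timecourse(ep, chunk_size=5, n_iter=2, seed=7, time_step=4), "category"
    )
    t_common = np.intersect1d(tg.time_ms, cat.time_ms)
    diag = np.diag(tg.accuracy)[np.isin(tg.time_ms, t_common)]
    curve = cat.accuracy[np.isin(cat.time_ms, t_common)]
    r = np.corrcoef(diag, curve)[0, 1]
    assert r > 0.5
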