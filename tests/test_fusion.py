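"""RDM construction, Spearman fusion, difference waves, onset extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import imfusion as im
from imfusion.bayes import EvidenceSeries
from imfusion.fusion import EegRdmSeries, FusionTimeseries, onset_latency
from imfusion.rdm import RDM, correlation_rdm, lower_triangle
from imfusion.synth import RoiBetaSet

from conftest import epochs_from_array, small_truth


def _beta_set(values):
    return RoiBetaSet(roi="R", hemisphere="lh", betas=values)


# ----------------------------------------------------------------------- RDM


def test_correlation_rdm_trivial_entries():
    rng = np.random.default_rng(0)
    base = rng.standard_normal(50)
    patterns = np.stack([base, base.copy(), -(base - base.mean()) + 5.0])
    d = correlation_rdm(patterns)
    assert d[0, 1] == pytest.approx(0.0, abs=1e-12)  # identical
    assert d[0, 2] == pytest.approx(2.0, abs=1e-12)  # anti-correlated
    assert np.allclose(np.diag(d), 0.0)


def test_fmri_rdm_matches_brute_force_pearson():
    rng = np.random.default_rng(1)
    betas = rng.standard_normal((50, 12))
    d = im.fmri_rdm(_beta_set(betas)).values
    for i in range(12):
        for j in range(12):
            expected = 0.0 if i == j else 1.0 - np.corrcoef(betas[:, i], betas[:, j])[0, 1]
            assert d[i, j] == pytest.approx(expected, abs=1e-10)


def test_rdm_invariance_to_offset_and_scale():
    rng = np.random.default_rng(2)
    betas = rng.standard_normal((30, 12))
    d0 = im.fmri_rdm(_beta_set(betas)).values
    d1 = im.fmri_rdm(_beta_set(3.0 * betas + 7.0)).values
    assert np.allclose(d0, d1, atol=1e-10)


def test_zero_variance_pattern_flagged_as_sentinel():
    rng = np.random.default_rng(3)
    betas = rng.standard_normal((20, 12))
    betas[:, 4] = 2.5  # constant pattern: correlation undefined
    d = im.fmri_rdm(_beta_set(betas)).values
    assert np.isnan(d[4, :]).sum() == 11 and d[4, 4] == 0.0
    assert np.isfinite(d[np.ix_([0, 1], [2, 3])]).all()


def test_rdm_container_validation():
    with pytest.raises(ValueError):
        RDM(values=np.ones((12, 12)))  # non-zero diagonal
    bad = np.zeros((12, 12))
    bad[0, 1] = 1.0
    with pytest.raises(ValueError):
        RDM(values=bad)  # asymmetric


# ------------------------------------------------------------------ EEG RDMs


def test_eeg_rdm_count_and_brute_force():
    rng = np.random.default_rng(4)
    n_cond, n_trials, n_ch, n_t = 4, 6, 5, 7
    conds = np.repeat(np.arange(1, n_cond + 1), n_trials)
    data = rng.standard_normal((len(conds), n_ch, n_t))
    ep = epochs_from_array(data, conds)
    series = im.eeg_rdm_timeseries(ep)
    assert len(series) == n_t
    means = np.stack([data[conds == c].mean(axis=0) for c in range(1, n_cond + 1)])
    for t in range(n_t):
        for i in range(n_cond):
            for j in range(i + 1, n_cond):
                expected = 1.0 - np.corrcoef(means[i, :, t], means[j, :, t])[0, 1]
                assert series.values[t, i, j] == pytest.approx(expected, abs=1e-10)


def test_identical_mean_topographies_give_zero_entry():
    data = np.ones((4, 3, 2))
    data[:, :, :] = np.arange(3)[None, :, None]  # same topography everywhere
    ep = epochs_from_array(data, np.array([1, 1, 2, 2]), n_people=1)
    series = im.eeg_rdm_timeseries(ep)
    assert series.values[0, 0, 1] == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------------------- fuse


def _series_from_matrices(mats):
    mats = np.asarray(mats, dtype=float)
    return EegRdmSeries(time_ms=np.arange(len(mats), dtype=float), values=mats)


def test_fuse_perfect_and_reversed_rank_agreement():
    rng = np.random.default_rng(5)
    roi = im.fmri_rdm(_beta_set(rng.standard_normal((30, 12))))
    v = roi.vector()
    reversed_rdm = im.rdm.squareform_vector(v.max() + v.min() - v, 12)
    series = _series_from_matrices([roi.values, reversed_rdm])
    out = im.fuse(series, roi)
    assert out.rho[0] == pytest.approx(1.0)
    assert out.rho[1] == pytest.approx(-1.0)


def test_fuse_matches_scipy_spearman_with_ties():
    rng = np.random.default_rng(6)
    roi_vals = im.rdm.squareform_vector(rng.integers(0, 5, 66).astype(float), 12)
    mats = [im.rdm.squareform_vector(rng.integers(0, 4, 66).astype(float), 12) for _ in range(6)]
    out = im.fuse(_series_from_matrices(mats), RDM(values=roi_vals))
    for t, m in enumerate(mats):
        ref = stats.spearmanr(lower_triangle(m), lower_triangle(roi_vals)).statistic
        assert out.rho[t] == pytest.approx(ref, abs=1e-12)


def test_fuse_invariant_to_monotone_transforms():
    rng = np.random.default_rng(7)
    roi = im.fmri_rdm(_beta_set(rng.standard_normal((25, 12))))
    mats = [correlation_rdm(rng.standard_normal((12, 20))) for _ in range(3)]
    base = im.fuse(_series_from_matrices(mats), roi).rho
    warped = [np.expm1(2.0 * m) for m in mats]  # strictly increasing map
    assert np.allclose(im.fuse(_series_from_matrices(warped), roi).rho, base, atol=1e-12)
    roi_warped = RDM(values=np.sqrt(roi.values))
    assert np.allclose(im.fuse(_series_from_matrices(mats), roi_warped).rho, base, atol=1e-12)


def test_fuse_drops_sentinel_pairs_and_needs_five():
    rng = np.random.default_rng(8)
    roi_vals = correlation_rdm(rng.standard_normal((12, 20)))
    eeg = correlation_rdm(rng.standard_normal((12, 20)))
    eeg_bad = eeg.copy()
    eeg_bad[0, :] = np.nan
    eeg_bad[:, 0] = np.nan
    np.fill_diagonal(eeg_bad, 0.0)
    out = im.fuse(_series_from_matrices([eeg_bad]), RDM(values=roi_vals))
    keep = np.isfinite(lower_triangle(eeg_bad))
    ref = stats.spearmanr(
        lower_triangle(eeg_bad)[keep], lower_triangle(roi_vals)[keep]
    ).statistic
    assert out.rho[0] == pytest.approx(ref, abs=1e-12)
    all_bad = np.full((12, 12), np.nan)
    np.fill_diagonal(all_bad, 0.0)
    assert np.isnan(im.fuse(_series_from_matrices([all_bad]), RDM(values=roi_vals)).rho[0])


# ------------------------------------------------- averaging and differences


def _fts(rho, subject=0, roi="A", hemi="lh"):
    return FusionTimeseries(
        time_ms=np.arange(len(rho), dtype=float), rho=np.asarray(rho, float),
        subject=subject, roi=roi, hemisphere=hemi,
    )


def test_hemisphere_average_elementwise_mean():
    lh = _fts([0.2, 0.0, -0.4])
    rh = _fts([0.4, 0.0, 0.2], hemi="rh")
    avg = im.hemisphere_average(lh, rh)
    assert np.allclose(avg.rho, [0.3, 0.0, -0.1])
    assert avg.hemisphere == "avg"
    assert np.allclose(im.hemisphere_average(lh, lh).rho, lh.rho)
    with pytest.raises(ValueError):
        im.hemisphere_average(lh, _fts([0.1, 0.2, 0.3], subject=1, hemi="rh"))


def test_difference_wave_antisymmetry_and_subject_check():
    rng = np.random.default_rng(9)
    a = _fts(rng.uniform(-0.5, 0.5, 10), roi="A")
    b = _fts(rng.uniform(-0.5, 0.5, 10), roi="B")
    dab = im.difference_wave(a, b)
    dba = im.difference_wave(b, a)
    assert np.allclose(dab.values, -dba.values)
    assert np.allclose(im.difference_wave(a, a).values, 0.0)
    assert dab.pair == "A-B"
    with pytest.raises(ValueError):
        im.difference_wave(a, _fts(np.zeros(10), subject=2, roi="B"))


# ------------------------------------------------------------------- onsets


def _evidence(bf, dt=4.0):
    return EvidenceSeries(
        time_ms=dt * np.arange(len(bf)), bf10=np.asarray(bf, float), direction="greater"
    )


def test_onset_none_when_all_below_threshold():
    res = onset_latency(_evidence(np.full(50, 2.9)))
    assert res.onset_ms is None and len(res.clusters) == 0


def test_onset_at_start_of_first_long_cluster():
    bf = np.ones(300)
    bf[125:150] = 10.0  # 500 ms at dt=4
    res = onset_latency(_evidence(bf, dt=4.0))
    assert res.onset_ms == 500.0
    assert res.onset_imagery_ms == 0.0


def test_short_clusters_are_tabulated_but_do_not_qualify():
    bf = np.ones(100)
    bf[10:12] = 5.0   # 2 samples = 8 ms < 12 ms minimum
    bf[40:44] = 5.0   # 4 samples = 16 ms qualifies
    res = onset_latency(_evidence(bf, dt=4.0), min_duration_ms=12.0)
    assert len(res.clusters) == 2
    assert res.onset_ms == 160.0


def test_cluster_table_matches_brute_force_run_scan():
    rng = np.random.default_rng(10)
    bf = np.where(rng.random(200) < 0.3, 10.0, 0.5)
    res = onset_latency(_evidence(bf, dt=2.0), min_duration_ms=0.0)
    # independent run-length scan
    runs = []
    start = None
    for i, above in enumerate(bf > 3.0):
        if above and start is None:
            start = i
        if not above and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(bf) - 1))
    assert len(res.clusters) == len(runs)
    for (s, e), row in zip(runs, res.clusters.itertuples()):
        assert row.start_ms == 2.0 * s and row.end_ms == 2.0 * e
        assert row.n_samples == e - s + 1


def test_fusion_count_audit_nine_rois_two_hemispheres():
    truth = small_truth()
    rdms = [
        im.fmri_rdm(im.generate_roi_betas(truth, r, h))
        for r in truth.rois
        for h in ("lh", "rh")
    ]
    assert len(rdms) == 18
    assert all(r.values.shape == (12, 12) for r in rdms)
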