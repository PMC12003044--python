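"""Bayesian t-tests against an independent quadrature oracle; BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import imfusion as im
from imfusion.bayes import (
    ALTERNATIVE,
    INCONCLUSIVE,
    NULL,
    bf_from_t,
    bh_fdr,
    classify_evidence,
    evidence_timeseries,
)


def oracle_bf(t, n, r=0.5, w=0.707, direction="greater", null_mode="point"):
    """Brute-force trapezoid evaluation of the Bayes-factor integrals.

    Written independently of the package's Gauss-Legendre implementation:
    plain dense grids in effect-size space.
    """
    df, sn = n - 1, np.sqrt(n)

    def tail(tt):
        hi = max(60.0, abs(tt) / sn + 60.0)
        d = np.linspace(r, hi, 120_001)
        f = stats.nct.pdf(tt, df, d * sn) * stats.cauchy.pdf(d, scale=w)
        return np.trapezoid(f, d)

    mass = 1.0 - stats.cauchy.cdf(r, scale=w)
    if direction == "greater":
        m1 = tail(t) / mass
    elif direction == "less":
        m1 = tail(-t) / mass
    else:
        m1 = (tail(t) + tail(-t)) / (2.0 * mass)
    if null_mode == "point":
        m0 = stats.t.pdf(t, df)
    else:
        d = np.linspace(-r, r, 60_001)
        f = stats.nct.pdf(t, df, d * sn) * stats.cauchy.pdf(d, scale=w)
        m0 = np.trapezoid(f, d) / (stats.cauchy.cdf(r, scale=w) - stats.cauchy.cdf(-r, scale=w))
    return m1 / m0


@pytest.mark.parametrize("n", [5, 12, 30])
def test_bf_matches_quadrature_oracle(n):
    for t in (-10.0, -1.0, 0.0, 0.5, 2.0, 5.0, 10.0):
        got = bf_from_t(t, n)
        ref = oracle_bf(t, n)
        assert abs(got - ref) / ref < 1e-4


def test_bf_directions_and_interval_null_match_oracle():
    for direction in ("less", "two-sided"):
        got = bf_from_t(2.5, 12, direction=direction)
        assert abs(got - oracle_bf(2.5, 12, direction=direction)) / got < 1e-4
    got = bf_from_t(3.0, 12, null_mode="interval")
    ref = oracle_bf(3.0, 12, null_mode="interval")
    assert abs(got - ref) / ref < 1e-4


def test_bf_monotone_in_t_for_tested_direction():
    ts = np.linspace(-6, 8, 40)
    bf = bf_from_t(ts, 12)
    assert np.all(np.diff(bf) > 0)


def test_mean_at_null_point_cannot_favour_alternative():
    assert bf_from_t(0.0, 12) < 1.0
    x = np.r_[np.ones(6), -np.ones(6)] * 0.7  # mean exactly 0
    assert im.bf_ttest(x) < 1.0


def test_shifted_sample_yields_strong_evidence():
    rng = np.random.default_rng(1)
    assert im.bf_ttest(rng.normal(2.0, 1.0, 12)) > 3.0


def test_null_samples_typically_support_the_null():
    bfs = [im.bf_ttest(np.random.default_rng(k).normal(0.0, 1.0, 12)) for k in range(60)]
    assert np.median(bfs) < 1.0 / 3.0


def test_bf_input_validation():
    with pytest.raises(ValueError):
        im.bf_ttest(np.full(12, 3.0))  # zero variance
    with pytest.raises(ValueError):
        im.bf_ttest(np.array([1.0, 2.0]))  # too few
    with pytest.raises(ValueError):
        bf_from_t(1.0, 12, direction="sideways")


def test_classification_thresholds():
    assert classify_evidence(10.0) == ALTERNATIVE
    assert classify_evidence(0.2) == NULL
    assert classify_evidence(1.0) == INCONCLUSIVE
    assert classify_evidence(3.0) == INCONCLUSIVE  # strict inequality
    assert list(classify_evidence(np.array([4.0, 0.1, 1.0]))) == [
        ALTERNATIVE, NULL, INCONCLUSIVE,
    ]
    with pytest.raises(ValueError):
        classify_evidence(0.0)


# ---------------------------------------------------------------------- FDR


def test_bh_fdr_trivial_cases():
    assert bh_fdr(np.full(10, 0.001), q=0.05).mask.all()
    none = bh_fdr(np.array([0.2, 0.5, 0.9]), q=0.05)
    assert not none.mask.any() and none.threshold == 0.0
    with pytest.raises(ValueError):
        bh_fdr(np.array([]))


def test_bh_fdr_matches_brute_force_step_up():
    p = np.array([0.01, 0.02, 0.30, 0.80])
    res = bh_fdr(p, q=0.05)
    # independent step-up evaluation
    order = np.argsort(p)
    m = len(p)
    k_max = 0
    for k, idx in enumerate(order, start=1):
        if p[idx] <= k * 0.05 / m:
            k_max = k
    expected = np.zeros(m, dtype=bool)
    expected[order[:k_max]] = True
    assert np.array_equal(res.mask, expected)
    assert res.threshold == pytest.approx(0.02)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30), st.randoms())
@settings(max_examples=40, deadline=None)
def test_bh_mask_is_monotone_and_permutation_invariant(pvals, pyrandom):
    p = np.asarray(pvals)
    res = bh_fdr(p, q=0.05)
    if res.mask.any():
        assert p[res.mask].max() <= p[~res.mask].min() if (~res.mask).any() else True
    perm = np.arange(len(p))
    pyrandom.shuffle(perm)
    res_p = bh_fdr(p[perm], q=0.05)
    assert np.array_equal(res_p.mask, res.mask[perm])


# ------------------------------------------------------------------- series


def test_evidence_series_grid_and_null_behaviour():
    rng = np.random.default_rng(2)
    t = np.arange(40.0)
    values = 0.01 * rng.standard_normal((8, 40))  # hovering at the null
    ev = evidence_timeseries(values, t, null_value=0.0, direction="greater")
    assert len(ev.bf10) == 40
    assert not (ev.labels == ALTERNATIVE).any()


def test_evidence_concentrates_in_planted_window():
    rng = np.random.default_rng(3)
    t = np.arange(60.0)
    values = rng.standard_normal((12, 60)) * 0.5
    values[:, 20:35] += 1.5
    ev = evidence_timeseries(values, t, null_value=0.0, direction="greater")
    inside = ev.labels[20:35] == ALTERNATIVE
    outside = ev.labels[np.r_[0:20, 35:60]] == ALTERNATIVE
    assert inside.mean() > 0.9
    assert outside.mean() < 0.1


def test_evidence_series_degenerate_handling():
    t = np.arange(5.0)
    values = np.tile(np.array([50.0, 50.0, 50.0, 60.0, 60.0]), (6, 1))
    values[:, :3] += 0.1 * np.random.default_rng(0).standard_normal((6, 3))
    with pytest.raises(ValueError):
        evidence_timeseries(values, t, null_value=50.0)
    ev = evidence_timeseries(values, t, null_value=50.0, on_degenerate="saturate")
    assert np.isinf(ev.bf10[3:]).all()
    with pytest.raises(ValueError):
        # degenerate AND exactly on the null point stays an error
        evidence_timeseries(np.full((6, 3), 50.0), np.arange(3.0), null_value=50.0,
                            on_degenerate="saturate")
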