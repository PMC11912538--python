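"""Weighted log-rank statistics, covariances, and stage increments.

The statistic is oriented so that positive values indicate benefit of the
experimental arm (expected minus observed events in that arm), which keeps
the one-sided cone, the stage-2 p-value and the planning drift consistent.
"""

import numpy as np
import pytest
from lifelines.statistics import logrank_test

from adaptlrt import (Cohort, DegenerateDataError, ScenarioSpec, WeightSpec,
                      fh_weight, kaplan_meier, simulate_cohort, snapshot,
                      stage_increment, wlr_stats)
from adaptlrt.wlrt import WLRStats


def brute_force_logrank_z(time, status, group):
    """Independent textbook log-rank: loop over distinct event times,
    accumulate (E - O) for the experimental arm and the variance
    sum d * (Y1/Y) * (1 - Y1/Y)."""
    num = var = 0.0
    for u in np.unique(time[status == 1]):
        at_risk = time >= u
        y, y1 = at_risk.sum(), (at_risk & (group == 1)).sum()
        d = ((time == u) & (status == 1)).sum()
        d1 = ((time == u) & (status == 1) & (group == 1)).sum()
        num += d * y1 / y - d1
        var += d * (y1 / y) * (1 - y1 / y)
    return num / np.sqrt(var)


def test_fh_weight_examples(hand_cohort):
    snap = snapshot(hand_cohort, 10.0)
    km = kaplan_meier(snap)
    s_first = 1.0  # first event time
    assert fh_weight(WeightSpec(0, 0), km, s_first) == 1.0
    assert fh_weight(WeightSpec(1, 0), km, s_first) == 0.0
    assert fh_weight(WeightSpec(0, 1), km, s_first) == 1.0
    # later event: left limits F(2-) = 0.25, S(2-) = 0.75
    assert fh_weight(WeightSpec(1, 0), km, 2.0) == pytest.approx(0.25)
    assert fh_weight(WeightSpec(0, 1), km, 2.0) == pytest.approx(0.75)


def test_weight_spec_validation():
    with pytest.raises(ValueError):
        WeightSpec(-1, 0)


def test_two_subject_hand_example():
    """Single control-arm event with both subjects at risk: the statistic
    is +(1/2)/sqrt(2) (benefit-positive orientation) with variance 1/8."""
    cohort = Cohort(entry_time=[0, 0], group=[0, 1], event_time=[1.0, 50.0])
    stats = wlr_stats(snapshot(cohort, 2.0), [WeightSpec(0, 0)])
    assert stats.T[0] == pytest.approx(0.5 / np.sqrt(2))
    assert stats.Sigma[0, 0] == pytest.approx(1 / 8)
    assert stats.n == 2


def test_degenerate_inputs_error():
    one_arm = Cohort(entry_time=[0, 0], group=[1, 1], event_time=[1, 2])
    with pytest.raises(DegenerateDataError):
        wlr_stats(snapshot(one_arm, 5.0), [WeightSpec(0, 0)])
    no_events = Cohort.from_observed([0, 0], [0, 1], [1, 2], [0, 0])
    with pytest.raises(DegenerateDataError):
        wlr_stats(snapshot(no_events, 5.0), [WeightSpec(0, 0)])


def test_logrank_matches_brute_force_and_lifelines(staggered_cohort):
    snap = snapshot(staggered_cohort, 5.0)
    stats = wlr_stats(snap, [WeightSpec(0, 0)])
    z = stats.standardized(0)
    z_oracle = brute_force_logrank_z(snap.time, np.asarray(snap.status),
                                     np.asarray(snap.group))
    assert z == pytest.approx(z_oracle, abs=1e-10)
    # lifelines uses the hypergeometric tie factor; identical without ties
    assert np.unique(snap.time[snap.status == 1]).size == \
        (snap.status == 1).sum()
    ll = logrank_test(snap.time[snap.group == 0], snap.time[snap.group == 1],
                      snap.status[snap.group == 0],
                      snap.status[snap.group == 1])
    assert z ** 2 == pytest.approx(ll.test_statistic, rel=1e-9)


def test_subject_relabeling_invariance(effect_cohort, rng):
    weights = [WeightSpec(0, 0), WeightSpec(1, 1)]
    snap = snapshot(effect_cohort, 5.0)
    perm = rng.permutation(snap.n)
    shuffled = Cohort(entry_time=np.zeros(snap.n), group=snap.group[perm],
                      event_time=np.where(snap.status[perm] == 1,
                                          snap.time[perm], np.inf),
                      dropout_time=np.where(snap.status[perm] == 0,
                                            snap.time[perm], np.inf))
    stats = wlr_stats(snap, weights)
    stats_perm = wlr_stats(snapshot(shuffled, snap.analysis_time), weights)
    np.testing.assert_allclose(stats.T, stats_perm.T, atol=1e-12)
    np.testing.assert_allclose(stats.Sigma, stats_perm.Sigma, atol=1e-12)


def test_group_swap_flips_sign(effect_cohort):
    weights = [WeightSpec(0, 0), WeightSpec(0, 1)]
    swapped = Cohort(entry_time=effect_cohort.entry_time,
                     group=1 - effect_cohort.group,
                     event_time=effect_cohort.event_time,
                     dropout_time=effect_cohort.dropout_time)
    s1 = wlr_stats(snapshot(effect_cohort, 5.0), weights)
    s2 = wlr_stats(snapshot(swapped, 5.0), weights)
    np.testing.assert_allclose(s1.T, -s2.T, atol=1e-12)
    np.testing.assert_allclose(s1.Sigma, s2.Sigma, atol=1e-12)


def test_nested_weight_lists_are_consistent(effect_cohort):
    full = [WeightSpec(0, 0), WeightSpec(1, 0), WeightSpec(0, 1)]
    sub = full[:2]
    snap = snapshot(effect_cohort, 5.0)
    s_full = wlr_stats(snap, full)
    s_sub = wlr_stats(snap, sub)
    np.testing.assert_array_equal(s_full.T[:2], s_sub.T)
    np.testing.assert_array_equal(s_full.Sigma[:2, :2], s_sub.Sigma)


def test_null_standardized_statistic_is_normal():
    """Under equal exponential arms the standardized statistic should be
    close to standard normal (mean ~ 0, variance ~ 1)."""
    reps, zs = 2000, []
    spec = ScenarioSpec(theta=0.0, n_per_group=200)
    for ss in np.random.SeedSequence(2024).spawn(reps):
        snap = snapshot(simulate_cohort(spec, rng=ss), 8.0)
        zs.append(wlr_stats(snap, [WeightSpec(0, 0)]).standardized(0))
    zs = np.array(zs)
    assert abs(zs.mean()) < 3 * zs.std() / np.sqrt(reps)
    assert abs(zs.var() - 1.0) < 0.1


def test_stage_increment_against_recomputation(effect_cohort):
    """The increment equals the by-hand rescale-and-difference of the raw
    statistics at the two analysis times."""
    weights = (WeightSpec(0, 0), WeightSpec(1, 1))
    s1 = wlr_stats(snapshot(effect_cohort, 5.0), weights)
    s2 = wlr_stats(snapshot(effect_cohort, 8.0), weights)
    inc, p2 = stage_increment(s1, s2, 1)
    scale = np.sqrt(s1.n / s2.n)
    manual = ((s2.T[1] - scale * s1.T[1])
              / np.sqrt(s2.Sigma[1, 1] - (s1.n / s2.n) * s1.Sigma[1, 1]))
    assert inc == pytest.approx(manual, abs=1e-12)
    from scipy.stats import norm
    assert p2 == pytest.approx(norm.sf(inc))


def test_stage_increment_from_empty_interim(effect_cohort):
    """With a zero interim statistic the increment is the standardized
    full statistic at the final analysis."""
    weights = (WeightSpec(0, 0),)
    s2 = wlr_stats(snapshot(effect_cohort, 8.0), weights)
    s1 = WLRStats(analysis_time=1.0, weights=weights, T=np.zeros(1),
                  Sigma=np.zeros((1, 1)), n=s2.n)
    inc, _ = stage_increment(s1, s2, 0)
    assert inc == pytest.approx(s2.standardized(0))


def test_stage_increment_zero_information_errors():
    """Identical snapshots at both analysis times carry no new data."""
    cohort = Cohort.from_observed([0] * 6, [0, 1] * 3,
                                  [1, 1.5, 2, 2.5, 3, 3.5], [1] * 6)
    weights = (WeightSpec(0, 0),)
    s1 = wlr_stats(snapshot(cohort, 10.0), weights)
    s2 = wlr_stats(snapshot(cohort, 12.0), weights)
    s2 = WLRStats(analysis_time=12.0, weights=weights, T=s2.T,
                  Sigma=s2.Sigma, n=s2.n)
    with pytest.raises(DegenerateDataError):
        stage_increment(s1, s2, 0)
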