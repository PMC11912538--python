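"""Planning machinery: at-risk probabilities, drift/variance integrals,
conditional error and power, and the stage-2 weight selection rule."""

import numpy as np
import pytest
from scipy.stats import norm

from adaptlrt import (FisherCombiner, InverseNormalCombiner,
                      PlanningAssumptions, ScenarioSpec, WeightSpec,
                      at_risk_prob, conditional_error, conditional_power,
                      drift_and_variance, select_weight, simulate_cohort,
                      snapshot, stage_increment, wlr_stats)
from adaptlrt.cond_power import fh_weight_limit, uniform_accrual
from adaptlrt.simulate import scenario_assumptions

LAM = -np.log(0.7)


def exponential_assumptions(lam0=LAM, lam1=LAM, n_total=1000,
                            accrual_end=6.0, t1=5.0, t2=8.0, r=0.5):
    def make(lam):
        return (lambda s: np.exp(-lam * np.asarray(s, dtype=float)),
                lambda s: lam * np.exp(-lam * np.asarray(s, dtype=float)),
                lambda s: np.full_like(np.asarray(s, dtype=float), lam))

    s0, f0, h0 = make(lam0)
    s1, f1, h1 = make(lam1)
    return PlanningAssumptions(accrual_cdf=uniform_accrual(accrual_end),
                               survival0=s0, density0=f0, hazard0=h0,
                               survival1=s1, density1=f1, hazard1=h1,
                               n_total=n_total, t1=t1, t2=t2, allocation=r)


def test_at_risk_prob_examples():
    a = exponential_assumptions(r=0.5)
    # s = 0: survival and dropout factors are 1
    assert at_risk_prob(a, 1, 3.0, 0.0) == pytest.approx(0.5 * 3 / 6)
    # s >= t with no accrual mass at 0
    assert at_risk_prob(a, 0, 3.0, 3.5) == 0.0
    # closed-form product at t=5, s=2
    assert at_risk_prob(a, 1, 5.0, 2.0) == pytest.approx(
        0.5 * (3 / 6) * np.exp(-2 * LAM))


def test_null_drift_vanishes():
    a = exponential_assumptions()
    for w in (WeightSpec(0, 0), WeightSpec(1, 1)):
        for t in (3.0, 8.0):
            xi, var = drift_and_variance(a, w, t)
            assert xi == pytest.approx(0.0, abs=1e-12)
            assert var > 0


def test_variance_closed_form_instant_accrual():
    """Balanced arms, everyone recruited at 0, unit weight: the variance
    integrand collapses to f(s)/4, so sigma2(t) = F(t)/4."""
    a = exponential_assumptions()
    a.accrual_cdf = lambda u: np.ones_like(np.asarray(u, dtype=float))
    _, var = drift_and_variance(a, lambda s: np.ones_like(s), 4.0)
    assert var == pytest.approx((1 - np.exp(-LAM * 4.0)) / 4, rel=1e-9)


def test_variance_matches_monte_carlo():
    """sigma2(t) equals the sampling variance of the scaled statistic
    (exponential null, FH(0,1), uniform accrual).

    The observed statistic is scaled by the *enrolled* count while sigma2
    is a full-cohort limit, so the comparison divides by the enrolled
    fraction F_R(t) (here 5/6 at the interim).
    """
    spec = ScenarioSpec(theta=0.0, n_per_group=1000)
    a = scenario_assumptions(spec)
    w = WeightSpec(0, 1)
    t = 5.0
    _, var = drift_and_variance(a, w, t)
    expected = var / a.accrual_cdf(t)
    reps = 2000
    ts = []
    for ss in np.random.SeedSequence(303).spawn(reps):
        snap = snapshot(simulate_cohort(spec, rng=ss), t)
        ts.append(wlr_stats(snap, [w]).T[0])
    ts = np.array(ts)
    mc_var = ts.var()
    # MC standard error of a sample variance via the fourth moment
    se = np.sqrt((np.mean((ts - ts.mean()) ** 4) - mc_var ** 2) / reps)
    assert abs(mc_var - expected) < 3 * se
    assert abs(np.mean(ts)) < 3 * ts.std() / np.sqrt(reps)


def test_fh_weight_limit_uses_pooled_cdf():
    a = exponential_assumptions(lam1=2 * LAM)
    q = fh_weight_limit(a, WeightSpec(1, 0))
    s = 1.7
    pooled = 1 - 0.5 * (np.exp(-LAM * s) + np.exp(-2 * LAM * s))
    assert q(s) == pytest.approx(pooled)


def test_conditional_error_fisher_example():
    assert conditional_error(0.01, FisherCombiner(), 0.0038) == \
        pytest.approx(0.38)


def test_conditional_error_inverse_normal_closed_form_vs_root():
    comb = InverseNormalCombiner()
    c, p1 = 0.023996, 0.1
    closed = conditional_error(p1, comb, c)
    expected = norm.sf(np.sqrt(2) * norm.isf(c) - norm.isf(p1))
    assert closed == pytest.approx(expected, rel=1e-12)
    assert closed == pytest.approx(0.0649, abs=2e-4)
    # generic root-finding on the combination function agrees
    generic = super(InverseNormalCombiner, comb).conditional_error(p1, c)
    assert generic == pytest.approx(closed, abs=1e-9)


def test_conditional_error_self_consistent_at_p1_equals_c():
    comb = InverseNormalCombiner()
    c = 0.023996
    a2 = conditional_error(c, comb, c)
    assert comb.combine(c, a2) == pytest.approx(c, abs=1e-12)


def test_conditional_error_monotone_in_p1():
    grid = np.linspace(0.005, 0.9, 40)
    for comb in (InverseNormalCombiner(), FisherCombiner()):
        vals = [conditional_error(p, comb, 0.024) for p in grid]
        assert np.all(np.diff(vals) <= 1e-12)


def test_conditional_power_degenerate_cases():
    a = exponential_assumptions()
    assert conditional_power(a, WeightSpec(0, 0), 1.0) == 1.0
    # zero drift under the null: CP equals the conditional error itself
    for a2 in (0.05, 0.3):
        assert conditional_power(a, WeightSpec(0, 0), a2) == \
            pytest.approx(a2, abs=1e-9)


def test_conditional_power_matches_simulated_rejection_rate():
    """The bivariate-normal planning formula (including the sqrt(n) drift
    factor) reproduces the simulated stage-2 rejection rate."""
    theta = -0.3
    spec = ScenarioSpec(theta=theta, n_per_group=500)
    a = scenario_assumptions(spec)
    alpha2 = 0.05
    w = WeightSpec(0, 0)
    cp = conditional_power(a, w, alpha2)
    reps, hits = 1500, 0
    for ss in np.random.SeedSequence(99).spawn(reps):
        cohort = simulate_cohort(spec, rng=ss)
        s1 = wlr_stats(snapshot(cohort, 5.0), [w])
        s2 = wlr_stats(snapshot(cohort, 8.0), [w])
        _, p2 = stage_increment(s1, s2, 0)
        hits += p2 <= alpha2
    rate = hits / reps
    se = np.sqrt(cp * (1 - cp) / reps)
    assert abs(rate - cp) < 3 * se


def test_variance_nondecreasing_in_t():
    a = exponential_assumptions(lam1=0.7 * LAM)
    for w in (WeightSpec(0, 0), WeightSpec(1, 1)):
        vals = [drift_and_variance(a, w, t)[1]
                for t in np.linspace(0.5, 8.0, 8)]
        assert np.all(np.diff(vals) >= -1e-12)


def test_drift_antisymmetric_under_group_swap():
    a = exponential_assumptions(lam0=LAM, lam1=0.6 * LAM)
    b = exponential_assumptions(lam0=0.6 * LAM, lam1=LAM)
    for w in (WeightSpec(0, 0), WeightSpec(0, 1)):
        xi_a, _ = drift_and_variance(a, w, 6.0)
        xi_b, _ = drift_and_variance(b, w, 6.0)
        assert xi_a == pytest.approx(-xi_b, rel=1e-9)
        assert xi_a > 0  # benefit direction is positive drift


def make_late_effect_assumptions(split=2.0, theta=-1.0):
    """Equal hazards before `split`, lower experimental hazard after."""
    lam = LAM

    def s0(s):
        return np.exp(-lam * np.asarray(s, dtype=float))

    def h1(s):
        s = np.asarray(s, dtype=float)
        return np.where(s < split, lam, lam * np.exp(theta))

    def s1(s):
        s = np.asarray(s, dtype=float)
        cum = lam * np.minimum(s, split) + lam * np.exp(theta) * np.clip(
            s - split, 0, None)
        return np.exp(-cum)

    return PlanningAssumptions(
        accrual_cdf=uniform_accrual(6.0),
        survival0=s0, density0=lambda s: lam * s0(s),
        hazard0=lambda s: np.full_like(np.asarray(s, dtype=float), lam),
        survival1=s1, density1=lambda s: h1(s) * s1(s), hazard1=h1,
        n_total=1000, t1=5.0, t2=8.0)


def test_select_weight_trivial_cases():
    a = exponential_assumptions()
    idx, _ = select_weight(a, [WeightSpec(0, 0)], 0.05)
    assert idx == 0
    # under the null every CP equals alpha2: smallest index wins the tie
    idx, cps = select_weight(a, [WeightSpec(0, 0), WeightSpec(1, 0)], 0.05)
    assert idx == 0
    np.testing.assert_allclose(cps, 0.05, atol=1e-9)


def test_select_weight_prefers_late_weight_for_late_effect():
    """A late-separation planning model should favour the late-emphasis
    weight FH(1,0) over the early-emphasis FH(0,1)."""
    a = make_late_effect_assumptions()
    cands = [WeightSpec(0, 1), WeightSpec(0, 0), WeightSpec(1, 0)]
    idx, cps = select_weight(a, cands, 0.05)
    assert cps[2] > cps[0]
    assert idx == int(np.argmax(cps))
    assert cands[idx] == WeightSpec(1, 0)
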