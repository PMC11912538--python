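"""Two-stage adaptive design: sequential bounds, the level condition, and
orchestration of a full two-stage analysis with interim weight selection.

The design tests equal survival against one-sided superiority of the
experimental arm.  Stage 1 applies the one-sided multi-directional
combination test (wild bootstrap p-value ``p1``); the trial stops for
efficacy if ``p1 <= alpha1`` and for futility if ``p1 > alpha0``.
Otherwise the interim data drive per-arm spline extrapolations, the
conditional error is computed from ``p1``, and the candidate weight with
the largest conditional power is frozen for stage 2.  The final decision
rejects iff ``C(p1, p2) <= c``, where ``p2`` comes from the standardized
increment of the selected weighted log-rank statistic.  The level
condition

    alpha = alpha1 + int_{alpha1}^{alpha0} int_0^1 1{C(p1,p2) <= c} dp2 dp1

ties the bounds together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from . import rp_spline
from .combination import Combiner, InverseNormalCombiner
from .cond_power import (PlanningAssumptions, conditional_error,
                         select_weight, uniform_accrual)
from .mdir import wild_bootstrap_p
from .trial_data import Cohort, snapshot
from .wlrt import WeightSpec, stage_increment, wlr_stats

__all__ = [
    "DesignSpec",
    "TrialResult",
    "combine",
    "obf_two_stage_bounds",
    "pocock_two_stage_bounds",
    "verify_level",
    "run_two_stage",
    "run_two_stage_fixed",
]

DEFAULT_CANDIDATES = (WeightSpec(0, 0), WeightSpec(1, 0),
                      WeightSpec(0, 1), WeightSpec(1, 1))

_SQRT2 = math.sqrt(2.0)
_BVN_COV = [[1.0, 1.0 / _SQRT2], [1.0 / _SQRT2, 1.0]]


def combine(combiner: Combiner, p1: float, p2: float) -> float:
    """Combined p-value ``C(p1, p2)``."""
    return combiner.combine(p1, p2)


def _two_stage_level(z: float) -> float:
    """Overall one-sided level of z-bounds ``(z*sqrt2, z)`` under
    independent standard normal increments with equal information."""
    # (Z1, (Z1+Z2)/sqrt2) is bivariate normal with correlation 1/sqrt2
    upper = norm.sf(z * _SQRT2)
    joint_low = multivariate_normal.cdf([z * _SQRT2, z], mean=[0.0, 0.0],
                                        cov=_BVN_COV)
    return upper + (norm.cdf(z * _SQRT2) - joint_low)


def obf_two_stage_bounds(alpha: float, alpha0: float = 1.0):
    """O'Brien-Fleming style bounds for a two-stage one-sided design.

    The z-scale bounds are ``(z*sqrt(2), z)`` with ``z`` solving the level
    condition under equally spaced information.  Returns
    ``(alpha1, c) = (1 - Phi(z*sqrt2), 1 - Phi(z))``.  A futility bound
    ``alpha0 < 1`` is treated as non-binding (the level remains controlled,
    conservatively).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z = brentq(lambda v: _two_stage_level(v) - alpha, 0.5, 8.0, xtol=1e-12)
    return float(norm.sf(z * _SQRT2)), float(norm.sf(z))


def pocock_two_stage_bounds(alpha: float):
    """Pocock-style bounds: a common z-bound at both analyses."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    def level(z):
        upper = norm.sf(z)
        joint_low = multivariate_normal.cdf([z, z], mean=[0.0, 0.0],
                                            cov=_BVN_COV)
        return upper + (norm.cdf(z) - joint_low)

    z = brentq(lambda v: level(v) - alpha, 0.5, 8.0, xtol=1e-12)
    p = float(norm.sf(z))
    return p, p


@dataclass
class DesignSpec:
    """Two-stage design parameters.

    Defaults follow a one-sided level-0.025 O'Brien-Fleming two-stage plan
    with equally weighted inverse-normal combination, no futility bound,
    interim at year 5 and final analysis at year 8, uniform accrual over
    the first six years, and the four Fleming-Harrington weights
    (0,0), (1,0), (0,1), (1,1) as both the combination-test set and the
    stage-2 candidate set.
    """

    alpha: float = 0.025
    alpha0: float = 1.0
    alpha1: float = None  # type: ignore[assignment]
    c: float = None  # type: ignore[assignment]
    combiner: Combiner = field(default_factory=InverseNormalCombiner)
    mdir_weights: tuple = DEFAULT_CANDIDATES
    candidate_weights: tuple = DEFAULT_CANDIDATES
    t1: float = 5.0
    t2: float = 8.0
    n_boot: int = 1000
    spline_knot_counts: tuple = (0, 1, 2)
    spline_scales: tuple = rp_spline.SCALES
    accrual_end: float = 6.0
    allocation: float = 0.5

    def __post_init__(self):
        if self.alpha1 is None or self.c is None:
            a1, c = obf_two_stage_bounds(self.alpha, self.alpha0)
            self.alpha1 = a1 if self.alpha1 is None else self.alpha1
            self.c = c if self.c is None else self.c
        self.mdir_weights = tuple(self.mdir_weights)
        self.candidate_weights = tuple(self.candidate_weights)
        if len(set(self.mdir_weights)) != len(self.mdir_weights):
            raise ValueError("duplicate weights in the combination-test set")
        if not 0 < self.alpha1 <= self.alpha <= self.alpha0 <= 1:
            raise ValueError("bounds must satisfy 0 < alpha1 <= alpha "
                             "<= alpha0 <= 1")
        if not self.t1 < self.t2:
            raise ValueError("t1 must precede t2")

    def validate(self, tol: float = 1e-4) -> float:
        """Check the level condition numerically; returns the attained level."""
        attained = verify_level(self)
        if abs(attained - self.alpha) > tol:
            raise ValueError(
                f"level condition violated: attained {attained:.6f} "
                f"!= nominal {self.alpha:.6f}")
        return attained


def verify_level(spec: DesignSpec) -> float:
    """Attained one-sided level of the design's bounds.

    Evaluates ``alpha1 + int_{alpha1}^{alpha0} A2(p1) dp1`` where the inner
    integral over ``p2`` is the conditional error in closed form.
    """
    val, _ = integrate.quad(
        lambda p1: conditional_error(p1, spec.combiner, spec.c),
        spec.alpha1, spec.alpha0, limit=200, epsabs=1e-10, epsrel=1e-10)
    return float(spec.alpha1 + val)


@dataclass
class TrialResult:
    """Full decision trace of one two-stage analysis."""

    decision: str  # stop_efficacy | stop_futility | reject_final | accept_final
    p1: float
    mdir_statistic: float
    selected_index: Optional[int] = None
    selected_weight: Optional[WeightSpec] = None
    S2: Optional[float] = None
    p2: Optional[float] = None
    combined: Optional[float] = None
    alpha_bounds: dict = field(default_factory=dict)
    conditional_error: Optional[float] = None
    cp_table: Optional[list] = None
    model_table: dict = field(default_factory=dict)
    seed: Optional[int] = None
    warnings: list = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return self.decision in ("stop_efficacy", "reject_final")

    @property
    def stopped_early(self) -> bool:
        return self.decision in ("stop_efficacy", "stop_futility")

    def to_dict(self) -> dict:
        d = {
            "decision": self.decision,
            "p1": self.p1,
            "mdir_statistic": self.mdir_statistic,
            "selected_index": self.selected_index,
            "selected_weight": (repr(self.selected_weight)
                                if self.selected_weight else None),
            "S2": self.S2,
            "p2": self.p2,
            "combined": self.combined,
            "alpha_bounds": self.alpha_bounds,
            "conditional_error": self.conditional_error,
            "cp_table": (None if self.cp_table is None
                         else [None if np.isnan(v) else float(v)
                               for v in self.cp_table]),
            "model_table": self.model_table,
            "seed": (self.seed if self.seed is None
                     or isinstance(self.seed, int) else str(self.seed)),
            "warnings": self.warnings,
        }
        return d


def _interim_planning(spec: DesignSpec, snap1, n_total, rng, notes):
    """Fit the spline grid per arm and build planning assumptions.

    Returns ``None`` if either arm has no valid fit (the caller then falls
    back to the neutral log-rank weight).
    """
    models = {}
    table = {}
    for arm in (0, 1):
        mask = snap1.group_mask(arm) & (snap1.time > 0)
        fits = rp_spline.fit_grid(snap1.time[mask], snap1.status[mask],
                                  knot_counts=spec.spline_knot_counts,
                                  scales=spec.spline_scales, rng=rng)
        table[f"group{arm}"] = [m.to_record() for m in fits]
        if not fits:
            notes.append(f"all spline fits failed for arm {arm}")
            return None, table
        models[arm] = rp_spline.select_by_aic(fits)
    assump = PlanningAssumptions.from_spline_models(
        models[0], models[1],
        accrual_cdf=uniform_accrual(spec.accrual_end),
        allocation=spec.allocation, n_total=n_total,
        t1=spec.t1, t2=spec.t2)
    return assump, table


def run_two_stage(cohort: Cohort, spec: DesignSpec, rng_seed=None,
                  check_level: bool = True) -> TrialResult:
    """Execute a full two-stage adaptive analysis on one cohort.

    Stage 1: combination test with wild bootstrap at ``t1`` and the stop
    checks.  On continuation: per-arm spline fits with AIC selection,
    conditional error from ``p1``, conditional-power selection of the
    stage-2 weight (all from ``t1``-observable data only), then the
    standardized increment at ``t2`` and the combined decision.
    """
    if check_level:
        spec.validate()
    seed_seq = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
                else np.random.SeedSequence(rng_seed))
    boot_ss, spline_ss = seed_seq.spawn(2)
    notes: list = []
    bounds = {"alpha": spec.alpha, "alpha0": spec.alpha0,
              "alpha1": spec.alpha1, "c": spec.c}

    snap1 = snapshot(cohort, spec.t1)
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        boot = wild_bootstrap_p(snap1, spec.mdir_weights,
                                n_boot=spec.n_boot,
                                rng=np.random.default_rng(boot_ss))
    notes.extend(str(w.message) for w in wrec)
    p1 = boot.p_value

    if p1 <= spec.alpha1:
        return TrialResult(decision="stop_efficacy", p1=p1,
                           mdir_statistic=boot.statistic,
                           alpha_bounds=bounds, seed=rng_seed,
                           warnings=notes)
    if p1 > spec.alpha0:
        return TrialResult(decision="stop_futility", p1=p1,
                           mdir_statistic=boot.statistic,
                           alpha_bounds=bounds, seed=rng_seed,
                           warnings=notes)

    alpha2 = conditional_error(p1, spec.combiner, spec.c)
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        assump, model_table = _interim_planning(
            spec, snap1, n_total=cohort.n,
            rng=np.random.default_rng(spline_ss), notes=notes)
    notes.extend(str(w.message) for w in wrec)

    cp_table = None
    if assump is None:
        # neutral fallback: the standard log-rank weight
        try:
            sel = spec.candidate_weights.index(WeightSpec(0, 0))
        except ValueError:
            sel = 0
        notes.append("spline planning unavailable; fell back to the "
                     "log-rank weight")
    else:
        sel, cp_vals = select_weight(assump, spec.candidate_weights, alpha2)
        cp_table = list(cp_vals)

    snap2 = snapshot(cohort, spec.t2)
    stats1 = wlr_stats(snap1, spec.candidate_weights)
    stats2 = wlr_stats(snap2, spec.candidate_weights)
    s2, p2 = stage_increment(stats1, stats2, sel)
    comb = combine(spec.combiner, p1, p2)
    decision = "reject_final" if comb <= spec.c else "accept_final"
    return TrialResult(decision=decision, p1=p1,
                       mdir_statistic=boot.statistic, selected_index=sel,
                       selected_weight=spec.candidate_weights[sel],
                       S2=s2, p2=p2, combined=comb, alpha_bounds=bounds,
                       conditional_error=alpha2, cp_table=cp_table,
                       model_table=model_table, seed=rng_seed,
                       warnings=notes)


def run_two_stage_fixed(cohort: Cohort, spec: DesignSpec,
                        weight: WeightSpec) -> TrialResult:
    """Two-stage design with one prespecified weighted log-rank test.

    Stage 1 uses the one-sided normal approximation of the standardized
    statistic; stage 2 the standardized increment.  No bootstrap, splines
    or selection are involved (the reference designs of the power study).
    """
    snap1 = snapshot(cohort, spec.t1)
    stats1 = wlr_stats(snap1, (weight,))
    z1 = stats1.standardized(0)
    p1 = float(norm.sf(z1))
    bounds = {"alpha": spec.alpha, "alpha0": spec.alpha0,
              "alpha1": spec.alpha1, "c": spec.c}
    if p1 <= spec.alpha1:
        return TrialResult(decision="stop_efficacy", p1=p1,
                           mdir_statistic=max(z1, 0.0) ** 2,
                           selected_index=0, selected_weight=weight,
                           alpha_bounds=bounds)
    if p1 > spec.alpha0:
        return TrialResult(decision="stop_futility", p1=p1,
                           mdir_statistic=max(z1, 0.0) ** 2,
                           selected_index=0, selected_weight=weight,
                           alpha_bounds=bounds)
    snap2 = snapshot(cohort, spec.t2)
    stats2 = wlr_stats(snap2, (weight,))
    s2, p2 = stage_increment(stats1, stats2, 0)
    comb = combine(spec.combiner, p1, p2)
    decision = "reject_final" if comb <= spec.c else "accept_final"
    return TrialResult(decision=decision, p1=p1,
                       mdir_statistic=max(z1, 0.0) ** 2, selected_index=0,
                       selected_weight=weight, S2=s2, p2=p2, combined=comb,
                       alpha_bounds=bounds)
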