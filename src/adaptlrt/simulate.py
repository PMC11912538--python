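"""Scenario generator and study runner for the two-stage design.

The stated trial world: subjects enter uniformly over the first six
calendar years, the control arm is exponential with an annual event rate
of 30% (hazard ``-log(0.7)``), there is no random dropout, and analyses
take place after 5 (interim) and 8 (final) years.  Alternatives are
built so that one particular Fleming-Harrington weight ``w(rho*, gamma*)``
is locally optimal: the log hazard ratio is proportional to that weight
evaluated at the control CDF,

    lam1(s) = lam0 * exp(theta * F0(s)^rho* * (1 - F0(s))^gamma*)

so ``theta = 0`` is the null, ``(0,0)`` gives exact proportional hazards
``lam1 = lam0 * e^theta``, and more negative ``theta`` means a larger
experimental-arm advantage.  Effect sizes are calibrated analytically so
the two-stage design with the matched weight attains a target power,
via the bivariate-normal independent-increments approximation with the
drift and variance integrals of the planning machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm
from statsmodels.stats.proportion import proportion_confint

from .cond_power import PlanningAssumptions, drift_and_variance, uniform_accrual
from .design import DesignSpec, run_two_stage, run_two_stage_fixed
from .trial_data import Cohort
from .wlrt import WeightSpec

__all__ = [
    "ScenarioSpec",
    "control_hazard_rate",
    "alt_functions",
    "scenario_assumptions",
    "simulate_cohort",
    "mc_rate_interval",
    "two_stage_power",
    "calibrate_theta0",
    "run_study",
]

#: control hazard for a 30% annual event rate
DEFAULT_LAMBDA0 = -math.log(1.0 - 0.3)

#: inversion grid: points and horizon margin beyond the final analysis
_GRID_SIZE = 4096
_GRID_MARGIN = 10.0


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario of the stated trial world."""

    rho_star: float = 0.0
    gamma_star: float = 0.0
    theta: float = 0.0
    n_per_group: int = 500
    accrual_end: float = 6.0
    lambda0: float = DEFAULT_LAMBDA0
    t1: float = 5.0
    t2: float = 8.0

    def __post_init__(self):
        if self.theta > 0:
            raise ValueError("theta must be <= 0 (0 = null)")
        if not self.t1 < self.t2:
            raise ValueError("t1 must precede t2")
        if self.accrual_end > self.t2:
            raise ValueError("accrual must end by the final analysis")
        if self.lambda0 <= 0:
            raise ValueError("control hazard must be positive")

    @property
    def optimal_weight(self) -> WeightSpec:
        return WeightSpec(self.rho_star, self.gamma_star)


def control_hazard_rate(spec: ScenarioSpec):
    """Control-arm (survival, density, hazard) callables."""
    lam = spec.lambda0

    def surv(s):
        return np.exp(-lam * np.asarray(s, dtype=float))

    def dens(s):
        return lam * surv(s)

    def haz(s):
        return np.full_like(np.asarray(s, dtype=float), lam)

    return surv, dens, haz


def _lambda1(spec: ScenarioSpec):
    lam0 = spec.lambda0
    w = spec.optimal_weight

    def haz(s):
        s = np.asarray(s, dtype=float)
        f0 = 1.0 - np.exp(-lam0 * s)
        return lam0 * np.exp(spec.theta * w.evaluate(f0, 1.0 - f0))

    return haz


def _cumhaz_grid(spec: ScenarioSpec):
    """Tabulated cumulative hazard of the experimental arm."""
    horizon = spec.t2 + _GRID_MARGIN
    s = np.concatenate(([0.0], np.geomspace(1e-6, horizon, _GRID_SIZE - 1)))
    lam = _lambda1(spec)(s)
    cum = np.concatenate(([0.0], np.cumsum(
        0.5 * (lam[1:] + lam[:-1]) * np.diff(s))))
    return s, cum


def alt_functions(spec: ScenarioSpec):
    """Experimental-arm (survival, density, hazard) callables.

    Proportional hazards ``(rho*, gamma*) = (0, 0)`` uses the closed form;
    otherwise the cumulative hazard is integrated numerically on a dense
    grid and interpolated.
    """
    haz = _lambda1(spec)
    if spec.rho_star == 0 and spec.gamma_star == 0:
        lam = spec.lambda0 * math.exp(spec.theta)

        def surv(s):
            return np.exp(-lam * np.asarray(s, dtype=float))

        def dens(s):
            return lam * surv(s)

        return surv, dens, haz

    sgrid, cumgrid = _cumhaz_grid(spec)
    tail_rate = float(_lambda1(spec)(sgrid[-1]))

    def cumhaz(s):
        s = np.asarray(s, dtype=float)
        inside = np.interp(s, sgrid, cumgrid)
        beyond = cumgrid[-1] + tail_rate * (s - sgrid[-1])
        return np.where(s <= sgrid[-1], inside, beyond)

    def surv(s):
        return np.exp(-cumhaz(s))

    def dens(s):
        return haz(s) * surv(s)

    return surv, dens, haz


def scenario_assumptions(spec: ScenarioSpec) -> PlanningAssumptions:
    """Exact planning assumptions matching the scenario's stated world."""
    s0, f0, h0 = control_hazard_rate(spec)
    s1, f1, h1 = alt_functions(spec)
    return PlanningAssumptions(
        accrual_cdf=uniform_accrual(spec.accrual_end),
        survival0=s0, density0=f0, hazard0=h0,
        survival1=s1, density1=f1, hazard1=h1,
        n_total=2 * spec.n_per_group, t1=spec.t1, t2=spec.t2,
        allocation=0.5)


def simulate_cohort(spec: ScenarioSpec, rng=None) -> Cohort:
    """Draw one cohort: uniform entries, balanced arms, inverted hazards."""
    rng = np.random.default_rng(rng)
    n = spec.n_per_group
    entry = rng.uniform(0.0, spec.accrual_end, size=2 * n)
    group = np.repeat(np.array([0, 1], dtype=np.int8), n)
    e = rng.exponential(size=2 * n)  # unit-rate exponentials to invert
    t_ctrl = e / spec.lambda0
    if spec.rho_star == 0 and spec.gamma_star == 0:
        t_exp = e / (spec.lambda0 * math.exp(spec.theta))
    else:
        sgrid, cumgrid = _cumhaz_grid(spec)
        tail_rate = float(_lambda1(spec)(sgrid[-1]))
        t_exp = np.interp(e, cumgrid, sgrid)
        over = e > cumgrid[-1]
        t_exp[over] = sgrid[-1] + (e[over] - cumgrid[-1]) / tail_rate
    event = np.where(group == 1, t_exp, t_ctrl)
    return Cohort(entry_time=entry, group=group,
                  event_time=np.maximum(event, 1e-12))


def mc_rate_interval(p: float, reps: int, level: float = 0.95):
    """Central normal-approximation interval for an empirical rate."""
    z = norm.isf((1.0 - level) / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / reps)
    return p - half, p + half


def two_stage_power(spec: ScenarioSpec, design: DesignSpec,
                    weight: Optional[WeightSpec] = None) -> float:
    """Analytic overall power of the fixed-weight two-stage design.

    Uses the independent-increments bivariate-normal approximation: the
    stage-1 z-value has mean ``sqrt(n) xi(t1)/sigma(t1)``, the stage-2
    increment mean ``sqrt(n) dxi/sqrt(dsigma2)``, and the design rejects
    when either the stage-1 z clears its bound or the inverse-normal
    combination clears the final bound.
    """
    weight = weight or spec.optimal_weight
    assump = scenario_assumptions(spec)
    xi1, v1 = drift_and_variance(assump, weight, spec.t1)
    xi2, v2 = drift_and_variance(assump, weight, spec.t2)
    dv = v2 - v1
    if v1 <= 0 or dv <= 0:
        raise ValueError("degenerate variance in the power approximation")
    rootn = math.sqrt(assump.n_total)
    mu1 = rootn * xi1 / math.sqrt(v1)
    mu2 = rootn * (xi2 - xi1) / math.sqrt(dv)
    comb = design.combiner
    w1 = getattr(comb, "w1", None)
    w2 = getattr(comb, "w2", None)
    if w1 is None:
        raise ValueError("analytic power requires the inverse-normal "
                         "combination")
    z1 = norm.isf(design.alpha1)
    zc = norm.isf(design.c)
    mean = [mu1, w1 * mu1 + w2 * mu2]
    cov = [[1.0, w1], [w1, 1.0]]
    accept = multivariate_normal.cdf([z1, zc], mean=mean, cov=cov)
    return float(1.0 - accept)


def calibrate_theta0(spec: ScenarioSpec, design: DesignSpec,
                     target_power: float = 0.5) -> float:
    """Solve for the effect size giving the target two-stage power.

    The matched weight ``w(rho*, gamma*)`` is used at both stages.  Power
    is monotone in ``-theta``; bisection brackets are grown geometrically.
    """
    if not design.alpha < target_power < 1:
        raise ValueError("target power must exceed the design level")

    def power(theta):
        return two_stage_power(replace(spec, theta=theta), design)

    lo = -0.5
    while power(lo) < target_power:
        lo *= 2.0
        if lo < -40:
            raise RuntimeError("no effect size attains the target power")
    return float(brentq(lambda th: power(th) - target_power, lo, -1e-9,
                        xtol=1e-6))


def _replicate(kind, spec, design, seed, fixed_weight):
    cohort = simulate_cohort(spec, rng=np.random.default_rng(seed))
    if kind == "adaptive":
        return run_two_stage(cohort, design, rng_seed=seed,
                             check_level=False)
    return run_two_stage_fixed(cohort, design, fixed_weight)


def run_study(spec: ScenarioSpec, design: DesignSpec, reps: int,
              seed=None, kind: str = "adaptive",
              fixed_weight: Optional[WeightSpec] = None,
              workers: int = 1) -> pd.DataFrame:
    """Empirical rejection rates over independent replicates.

    ``kind="adaptive"`` runs the full selection procedure per replicate;
    ``kind="fixed"`` the prespecified single-weight two-stage design.
    Replicates are independently seeded from a spawned stream per index,
    so results do not depend on the worker count.  Failed replicates are
    counted, not silently dropped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if kind not in ("adaptive", "fixed"):
        raise ValueError("kind must be 'adaptive' or 'fixed'")
    if kind == "fixed" and fixed_weight is None:
        fixed_weight = spec.optimal_weight
    if kind == "adaptive":
        design.validate()
    child_seeds = np.random.SeedSequence(seed).spawn(reps)

    def one(ss):
        try:
            return _replicate(kind, spec, design, ss, fixed_weight)
        except Exception as err:
            return err

    if workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=workers)(delayed(one)(ss)
                                           for ss in child_seeds)
    else:
        results = [one(ss) for ss in child_seeds]

    failures = sum(isinstance(r, Exception) for r in results)
    trials = [r for r in results if not isinstance(r, Exception)]
    n_ok = len(trials)
    rejected = sum(t.rejected for t in trials)
    early = sum(t.decision == "stop_efficacy" for t in trials)
    continued = [t for t in trials if not t.stopped_early]
    lo, hi = proportion_confint(rejected, max(n_ok, 1), alpha=0.05,
                                method="beta")
    row = {
        "kind": kind,
        "rho_star": spec.rho_star,
        "gamma_star": spec.gamma_star,
        "theta": spec.theta,
        "n_per_group": spec.n_per_group,
        "reps": reps,
        "failures": failures,
        "rejection_rate": rejected / n_ok if n_ok else np.nan,
        "ci_low": lo,
        "ci_high": hi,
        "early_rejection_rate": early / n_ok if n_ok else np.nan,
    }
    if kind == "adaptive":
        counts = {w: 0 for w in design.candidate_weights}
        for t in continued:
            if t.selected_weight is not None:
                counts[t.selected_weight] += 1
        denom = max(len(continued), 1)
        for w, cnt in counts.items():
            row[f"sel_{w!r}"] = cnt / denom if continued else np.nan
    return pd.DataFrame([row])
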