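"""Planning-time probability machinery: at-risk probabilities, drift and
variance of weighted log-rank statistics under assumed distributions,
conditional error/power, and the second-stage weight selection rule.

Under planning assumptions (accrual law, dropout law, allocation ratio and
per-arm survival models), the probability that a subject is in arm ``k``
and at risk ``s`` time units after entry when observed at calendar time
``t`` is

    pi_k(t, s) = P[Z=k] * F_R((t-s)+) * (1 - F_C(s)) * S_k(s)

The large-sample mean ("drift") and variance of the n^{-1/2}-scaled
weighted log-rank statistic are the integrals

    xi(t)     = int_0^t Q(s) pi0 pi1/(pi0+pi1) (lam0(s) - lam1(s)) ds
    sigma2(t) = int_0^t Q(s)^2 pi0 pi1/(pi0+pi1)^2
                * F_R((t-s)+) (1-F_C(s)) ((1-r) f0(s) + r f1(s)) ds

(the variance integrand's ratio has a squared denominator only: it is the
limit of (Y1/Y)(1-Y1/Y) times the pooled event intensity, and collapses to
1/4 in the balanced instant-accrual null case).  The standardized stage-2
increment is then approximately normal with mean

    sqrt(n) * (xi(t2) - xi(t1)) / sqrt(sigma2(t2) - sigma2(t1))

where ``n`` is the total number of randomized subjects: the scaling of the
observed statistic by the enrolled count cancels from the standardized
increment, leaving the full-sample factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .combination import Combiner, conditional_error  # noqa: F401  (re-export)
from .rp_spline import SplineModel
from .wlrt import WeightSpec

__all__ = [
    "PlanningAssumptions",
    "at_risk_prob",
    "fh_weight_limit",
    "drift_and_variance",
    "conditional_error",
    "conditional_power",
    "select_weight",
]


def no_dropout(s):
    return np.zeros_like(np.asarray(s, dtype=float))


def uniform_accrual(accrual_end: float) -> Callable:
    """CDF of entry times for uniform accrual on ``[0, accrual_end]``."""
    def cdf(u):
        return np.clip(np.asarray(u, dtype=float) / accrual_end, 0.0, 1.0)
    return cdf


@dataclass
class PlanningAssumptions:
    """Assumed laws used for conditional-power planning.

    ``survival0/1``, ``density0/1``, ``hazard0/1`` are vectorized callables
    of trial time (typically extrapolated spline models at the interim, or
    the exact scenario laws in the simulator).  ``allocation`` is
    ``r = P[Z=1]``; ``n_total`` the number of randomized subjects.
    """

    accrual_cdf: Callable
    survival0: Callable
    density0: Callable
    hazard0: Callable
    survival1: Callable
    density1: Callable
    hazard1: Callable
    n_total: int
    t1: float
    t2: float
    allocation: float = 0.5
    dropout_cdf: Callable = field(default=no_dropout)

    def __post_init__(self):
        if not 0 < self.allocation < 1:
            raise ValueError("allocation must lie strictly between 0 and 1")
        if not self.t1 < self.t2:
            raise ValueError("interim must precede the final analysis")

    @classmethod
    def from_spline_models(cls, model0: SplineModel, model1: SplineModel,
                           **kwargs) -> "PlanningAssumptions":
        return cls(survival0=model0.survival, density0=model0.density,
                   hazard0=model0.hazard, survival1=model1.survival,
                   density1=model1.density, hazard1=model1.hazard, **kwargs)

    def pooled_cdf(self, s):
        r = self.allocation
        return 1.0 - ((1 - r) * self.survival0(s) + r * self.survival1(s))


def at_risk_prob(assump: PlanningAssumptions, k: int, t, s):
    """``pi_k(t, s)``: probability of being in arm ``k`` and at risk."""
    s = np.asarray(s, dtype=float)
    pz = assump.allocation if k == 1 else 1.0 - assump.allocation
    sk = assump.survival1 if k == 1 else assump.survival0
    return (pz * assump.accrual_cdf(np.maximum(t - s, 0.0))
            * (1.0 - assump.dropout_cdf(s)) * sk(s))


def fh_weight_limit(assump: PlanningAssumptions, spec: WeightSpec) -> Callable:
    """Large-sample limit of a Fleming-Harrington weight.

    The empirical weight converges to ``w(rho,gamma)`` composed with the
    *pooled* event CDF, mixed by the allocation ratio.
    """
    def q(s):
        f = np.asarray(assump.pooled_cdf(s), dtype=float)
        return spec.evaluate(f, 1.0 - f)
    return q


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _integrate(fn, lo, hi, kinks):
    """Piecewise 64-point Gauss-Legendre over segments split at kinks.

    The integrand must be vectorized; segments are additionally split in
    half so spline-knot curvature is resolved.  Fixed-order quadrature on
    the smooth pieces reaches near machine precision and, unlike adaptive
    scalar quadrature, evaluates the integrand in a handful of array
    calls.
    """
    if hi <= lo:
        return 0.0
    pts = sorted(p for p in kinks if lo < p < hi)
    edges = np.array([lo, *pts, hi])
    # refine: split every segment into quarters
    edges = np.unique(np.concatenate(
        [np.linspace(edges[i], edges[i + 1], 5) for i in range(len(edges) - 1)]))
    mid = 0.5 * (edges[1:] + edges[:-1])
    half = 0.5 * (edges[1:] - edges[:-1])
    nodes = (mid[:, None] + half[:, None] * _GL_NODES).ravel()
    wts = (half[:, None] * _GL_WEIGHTS).ravel()
    vals = np.asarray(fn(nodes), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise RuntimeError("quadrature failed: non-finite integrand")
    return float(vals @ wts)


def drift_and_variance(assump: PlanningAssumptions, weight, t: float):
    """Drift ``xi(t)`` and variance ``sigma2(t)`` of one weighted statistic.

    ``weight`` is a :class:`WeightSpec` (its large-sample limit is formed
    from the assumed pooled CDF) or any callable of trial time.
    """
    q = (fh_weight_limit(assump, weight) if isinstance(weight, WeightSpec)
         else weight)
    r = assump.allocation

    def common(s):
        pi0 = at_risk_prob(assump, 0, t, s)
        pi1 = at_risk_prob(assump, 1, t, s)
        tot = pi0 + pi1
        return pi0, pi1, np.where(tot > 0, tot, np.inf)

    def drift_integrand(s):
        pi0, pi1, tot = common(s)
        return (q(s) * pi0 * pi1 / tot
                * (assump.hazard0(s) - assump.hazard1(s)))

    def var_integrand(s):
        pi0, pi1, tot = common(s)
        dens = ((1 - r) * assump.density0(s) + r * assump.density1(s))
        return (q(s) ** 2 * pi0 * pi1 / tot ** 2
                * assump.accrual_cdf(np.maximum(t - s, 0.0))
                * (1.0 - assump.dropout_cdf(s)) * dens)

    # F_R((t-s)+) has a kink where accrual saturates; help the quadrature
    kinks = _accrual_kinks(assump.accrual_cdf, t)
    xi = _integrate(drift_integrand, 0.0, t, kinks)
    sig2 = _integrate(var_integrand, 0.0, t, kinks)
    return xi, sig2


def _accrual_kinks(accrual_cdf, t):
    """Probe for the point where F_R((t-s)+) saturates at 1."""
    grid = np.linspace(0.0, t, 257)
    vals = np.asarray(accrual_cdf(np.maximum(t - grid, 0.0)))
    full = vals >= 1.0 - 1e-12
    if full.any() and not full.all():
        i = int(np.argmin(full))  # first index where accrual incomplete
        return [float(grid[max(i - 1, 0)])]
    return []


def conditional_power(assump: PlanningAssumptions, weight,
                      alpha2: float) -> float:
    """Probability that the stage-2 increment clears the conditional error.

    ``CP = 1 - Phi(Phi^{-1}(1 - alpha2) - sqrt(n) dxi / sqrt(dsigma2))``
    with the increments taken between the interim and final analysis.
    """
    if not 0 <= alpha2 <= 1:
        raise ValueError("alpha2 must lie in [0, 1]")
    if alpha2 == 1.0:
        return 1.0
    if alpha2 == 0.0:
        return 0.0
    xi1, s21 = drift_and_variance(assump, weight, assump.t1)
    xi2, s22 = drift_and_variance(assump, weight, assump.t2)
    dvar = s22 - s21
    if dvar <= 0:
        raise ValueError("nonpositive variance increment between analyses")
    mu = math.sqrt(assump.n_total) * (xi2 - xi1) / math.sqrt(dvar)
    return float(norm.sf(norm.isf(alpha2) - mu))


def select_weight(assump: PlanningAssumptions,
                  candidates: Sequence[WeightSpec],
                  alpha2: float):
    """Pick the candidate weight maximising conditional power.

    Returns ``(index, cp_values)``; ties and failed computations resolve to
    the smallest index among the maxima.  Raises if every candidate fails.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    cps = []
    for w in candidates:
        try:
            cps.append(conditional_power(assump, w, alpha2))
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"conditional power failed for {w}: {err}")
            cps.append(np.nan)
    arr = np.asarray(cps)
    if np.all(np.isnan(arr)):
        raise RuntimeError("conditional power failed for every candidate")
    idx = int(np.nanargmax(arr))
    return idx, arr
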