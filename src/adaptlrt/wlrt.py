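"""Weighted log-rank statistics with Fleming-Harrington weights.

The two-sample statistic at calendar time ``t`` is

    T_l = n^{-1/2} * sum_{events i} Q_l(X_i) * (Y1(X_i)/Y(X_i) - Z_i)

i.e. expected-minus-observed events in the experimental arm, so that
*positive* values indicate experimental-arm benefit (lower hazard).  This
orientation makes the one-sided cone restriction of the combination test,
the stage-2 p-value ``1 - Phi(S2)`` and the planning drift (which is
positive when the control hazard exceeds the experimental hazard) mutually
consistent.  The covariance estimator is

    Sigma_{l,l'} = n^{-1} * sum_{events i} Q_l Q_l' (Y1/Y)(1 - Y1/Y)

with everything evaluated at the observed event times.  Fleming-Harrington
weights ``Q(s) = F(s-)^rho * S(s-)^gamma`` use left limits of the pooled
Kaplan-Meier estimate; ``0^0 := 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .trial_data import Snapshot, StepSurvival

__all__ = [
    "WeightSpec",
    "WLRStats",
    "DegenerateDataError",
    "fh_weight",
    "wlr_stats",
    "wlr_residuals",
    "stage_increment",
]

#: numerical floor distinguishing a zero variance increment from noise
VAR_EPS = 1e-12


class DegenerateDataError(ValueError):
    """Raised when a snapshot carries no usable two-sample information."""


@dataclass(frozen=True, order=True)
class WeightSpec:
    """Fleming-Harrington weight ``w(rho, gamma)(u) = u^rho * (1-u)^gamma``.

    ``rho = gamma = 0`` is the classical log-rank weight; larger ``rho``
    emphasises late events, larger ``gamma`` early events.  Both parameters
    must be nonnegative so the weight is positive and the one-sided test
    remains valid.
    """

    rho: float
    gamma: float

    def __post_init__(self):
        if self.rho < 0 or self.gamma < 0:
            raise ValueError("rho and gamma must be nonnegative")
        object.__setattr__(self, "rho", float(self.rho))
        object.__setattr__(self, "gamma", float(self.gamma))

    def evaluate(self, cdf_left, surv_left):
        """Evaluate the weight from left-limit CDF/survival values."""
        cdf_left = np.asarray(cdf_left, dtype=float)
        surv_left = np.asarray(surv_left, dtype=float)
        out = np.ones(np.broadcast(cdf_left, surv_left).shape)
        if self.rho > 0:
            out = out * cdf_left ** self.rho
        if self.gamma > 0:
            out = out * surv_left ** self.gamma
        return out

    def __repr__(self):  # compact: FH(1,0)
        def fmt(v):
            return f"{v:g}"
        return f"FH({fmt(self.rho)},{fmt(self.gamma)})"


@dataclass(frozen=True)
class WLRStats:
    """Vector of weighted log-rank statistics at one analysis time.

    ``T`` is the ``n^{-1/2}``-scaled statistic vector (one entry per
    weight), ``Sigma`` the matching covariance estimate, and ``n`` the
    number of subjects enrolled by the analysis time (the scaling ``n``).
    """

    analysis_time: float
    weights: tuple
    T: np.ndarray
    Sigma: np.ndarray
    n: int

    def __post_init__(self):
        m = len(self.weights)
        if self.T.shape != (m,) or self.Sigma.shape != (m, m):
            raise ValueError("inconsistent statistic dimensions")

    def standardized(self, d: int = 0) -> float:
        """One-sided z-value ``T_d / sqrt(Sigma_dd)``."""
        v = self.Sigma[d, d]
        if v <= 0:
            raise DegenerateDataError("zero variance for requested weight")
        return float(self.T[d] / math.sqrt(v))


def fh_weight(spec: WeightSpec, pooled_km: StepSurvival, s) -> np.ndarray:
    """Fleming-Harrington weight at trial time(s) ``s``.

    Uses the left limit of the pooled Kaplan-Meier curve, i.e. the value
    strictly before any tie block at ``s``.
    """
    s_left = pooled_km.left_limit(s)
    return spec.evaluate(1.0 - np.asarray(s_left), s_left)


def _weighted_event_terms(snap: Snapshot, weights: Sequence[WeightSpec]):
    """Shared event-table computation for statistics and residuals.

    Returns the distinct event times, per-time weights ``W[l, j]``, event
    counts ``d_j`` and ``d1_j``, risk fractions ``p1_j = Y1_j/Y_j``.
    """
    if len(weights) == 0:
        raise ValueError("at least one weight is required")
    time, status, group = snap.time, snap.status, snap.group
    if not ((group == 0).any() and (group == 1).any()):
        raise DegenerateDataError("both groups must be present")
    d = status.astype(bool)
    if not d.any():
        raise DegenerateDataError("no events observed")
    et = np.unique(time[d])
    tsorted = np.sort(time)
    y = time.size - np.searchsorted(tsorted, et, side="left")
    t1sorted = np.sort(time[group == 1])
    y1 = t1sorted.size - np.searchsorted(t1sorted, et, side="left")
    te = np.sort(time[d])
    dcount = (np.searchsorted(te, et, side="right")
              - np.searchsorted(te, et, side="left")).astype(float)
    te1 = np.sort(time[d & (group == 1)])
    d1count = (np.searchsorted(te1, et, side="right")
               - np.searchsorted(te1, et, side="left")).astype(float)
    # pooled KM left limits at the distinct event times
    surv_after = np.cumprod(1.0 - dcount / y)
    surv_left = np.concatenate(([1.0], surv_after[:-1]))
    cdf_left = 1.0 - surv_left
    wmat = np.stack([w.evaluate(cdf_left, surv_left) for w in weights])
    return et, wmat, dcount, d1count, y1 / y


def wlr_stats(snap: Snapshot, weights: Sequence[WeightSpec]) -> WLRStats:
    """Weighted log-rank statistic vector and covariance on a snapshot.

    Requires both arms present and at least one event; raises
    :class:`DegenerateDataError` otherwise.
    """
    weights = tuple(weights)
    _, wmat, dcount, d1count, p1 = _weighted_event_terms(snap, weights)
    n = snap.n
    T = wmat @ (dcount * p1 - d1count) / math.sqrt(n)
    v = dcount * p1 * (1.0 - p1)
    Sigma = (wmat * v) @ wmat.T / n
    Sigma = 0.5 * (Sigma + Sigma.T)
    return WLRStats(analysis_time=snap.analysis_time, weights=weights,
                    T=T, Sigma=Sigma, n=n)


def wlr_residuals(snap: Snapshot, weights: Sequence[WeightSpec]):
    """Per-event-subject integrated residuals (for the wild bootstrap).

    Row ``i`` of the returned matrix is subject ``i``'s term
    ``Q_l(X_i) * (Y1/Y - Z_i)`` of the statistic sum; the statistic equals
    ``n^{-1/2}`` times the column sum.  Subjects without an observed event
    have a zero residual and are omitted.
    """
    weights = tuple(weights)
    et, wmat, _, _, p1 = _weighted_event_terms(snap, weights)
    d = snap.status.astype(bool)
    j = np.searchsorted(et, snap.time[d])
    z = snap.group[d].astype(float)
    return (wmat[:, j] * (p1[j] - z)).T  # (n_events, m)


def stage_increment(stats1: WLRStats, stats2: WLRStats, d: int):
    """Standardized stage-2 increment of one weighted log-rank statistic.

    Both inputs must come from the same ordered weight list; the interim
    statistic is rescaled to the final-analysis ``n`` before differencing
    so the increment telescopes.  Returns ``(S2, p2)`` with
    ``p2 = 1 - Phi(S2)``.
    """
    if stats1.weights != stats2.weights:
        raise ValueError("stage statistics use different weight lists")
    if stats2.analysis_time <= stats1.analysis_time:
        raise ValueError("final analysis must be later than the interim")
    if not 0 <= d < len(stats2.weights):
        raise IndexError("weight index out of range")
    scale = stats1.n / stats2.n
    t1 = stats1.T[d] * math.sqrt(scale)
    v1 = stats1.Sigma[d, d] * scale
    num = stats2.T[d] - t1
    dv = stats2.Sigma[d, d] - v1
    if dv <= VAR_EPS:
        raise DegenerateDataError(
            "no second-stage information (variance increment <= 0)")
    s2 = float(num / math.sqrt(dv))
    return s2, float(norm.sf(s2))
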