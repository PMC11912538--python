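"""Flexible parametric survival models on spline-transformed scales.

A link-transformed survival function ``g(S(t))`` is modelled as a natural
cubic spline ``eta(x)`` in log time ``x = log t``:

* ``hazard`` scale: ``g(u) = log(-log u)``  (0 internal knots = Weibull)
* ``odds`` scale:   ``g(u) = log(1/u - 1)`` (0 internal knots = log-logistic)
* ``normal`` scale: ``g(u) = -Phi^{-1}(u)`` (0 internal knots = lognormal)

Boundary knots sit at the smallest and largest uncensored log survival
times; ``p`` internal knots sit at the evenly spaced centiles of the
uncensored log times.  The natural-spline truncated-power basis is linear
beyond the boundary knots, which is what makes extrapolation of the fitted
curve well defined.  Fitting maximises the right-censored log-likelihood;
``eta`` must be nondecreasing (a valid hazard), enforced with a soft
barrier during optimisation and a hard grid check afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_logpdf(x):
    return -0.5 * x * x - _LOG_SQRT_2PI

__all__ = [
    "SCALES",
    "SplineFitError",
    "SplineModel",
    "spline_basis",
    "spline_basis_deriv",
    "fit_rp",
    "fit_grid",
    "select_by_aic",
    "model_functions",
]

SCALES = ("hazard", "odds", "normal")
_SCALE_ORDER = {s: i for i, s in enumerate(SCALES)}

#: hard-check grid size and margin beyond the boundary knots (log-time)
_MONO_GRID = 512
_MONO_MARGIN = 2.0
_BARRIER = 1e4


class SplineFitError(RuntimeError):
    """Raised when a spline model cannot be fitted validly."""


def spline_basis(x, internal_knots, boundary_knots) -> np.ndarray:
    """Natural cubic spline basis ``(1, x, v_1(x), ..., v_p(x))``.

    ``v_j(x) = (x-k_j)^3_+ - l_j (x-kmin)^3_+ - (1-l_j)(x-kmax)^3_+`` with
    ``l_j = (kmax-k_j)/(kmax-kmin)``; the cubic and quadratic terms cancel
    outside the boundary knots, so the basis is linear there.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = boundary_knots
    cols = [np.ones_like(x), x]
    for kj in internal_knots:
        lam = (kmax - kj) / (kmax - kmin)
        v = (np.clip(x - kj, 0, None) ** 3
             - lam * np.clip(x - kmin, 0, None) ** 3
             - (1 - lam) * np.clip(x - kmax, 0, None) ** 3)
        cols.append(v)
    return np.column_stack(cols)


def spline_basis_deriv(x, internal_knots, boundary_knots) -> np.ndarray:
    """Derivative of :func:`spline_basis` with respect to ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kmin, kmax = boundary_knots
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in internal_knots:
        lam = (kmax - kj) / (kmax - kmin)
        v = 3 * (np.clip(x - kj, 0, None) ** 2
                 - lam * np.clip(x - kmin, 0, None) ** 2
                 - (1 - lam) * np.clip(x - kmax, 0, None) ** 2)
        cols.append(v)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineModel:
    """A fitted spline survival model on one link scale.

    ``coeffs`` has length ``p + 2``; ``aic = -2 loglik + 2 (p + 2)``.
    The model evaluates survival, density and hazard at any positive time,
    including extrapolation beyond the data range (the transformed survival
    continues with its boundary slope).
    """

    scale: str
    boundary_knots: tuple
    internal_knots: tuple
    coeffs: np.ndarray
    loglik: float
    aic: float

    @property
    def n_params(self) -> int:
        return len(self.coeffs)

    def eta(self, x):
        return spline_basis(x, self.internal_knots,
                            self.boundary_knots) @ self.coeffs

    def eta_deriv(self, x):
        return spline_basis_deriv(x, self.internal_knots,
                                  self.boundary_knots) @ self.coeffs

    def log_survival(self, s):
        scalar = np.ndim(s) == 0
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.zeros_like(s)
        pos = s > 0
        eta = self.eta(np.log(s[pos]))
        if self.scale == "hazard":
            out[pos] = -np.exp(eta)
        elif self.scale == "odds":
            out[pos] = -np.logaddexp(0.0, eta)
        else:
            out[pos] = log_ndtr(-eta)
        return float(out[0]) if scalar else out

    def survival(self, s):
        res = np.exp(self.log_survival(s))
        return float(res) if np.ndim(s) == 0 else res

    def hazard(self, s):
        scalar = np.ndim(s) == 0
        s = np.atleast_1d(np.asarray(s, dtype=float))
        x = np.log(np.maximum(s, 1e-300))
        eta = self.eta(x)
        etap = self.eta_deriv(x)
        if self.scale == "hazard":
            h = np.exp(eta) * etap / s
        elif self.scale == "odds":
            # h = f/S with S = 1/(1+e^eta): e^eta etap / ((1+e^eta) s)
            h = np.exp(eta - np.logaddexp(0.0, eta)) * etap / s
        else:
            h = np.exp(_norm_logpdf(eta) - log_ndtr(-eta)) * etap / s
        res = np.where(s > 0, h, 0.0)
        return float(res[0]) if scalar else res

    def density(self, s):
        res = np.asarray(self.hazard(s)) * np.exp(self.log_survival(s))
        return float(res) if np.ndim(s) == 0 else res

    def to_record(self) -> dict:
        """Structured text record for trial-result traces."""
        return {
            "scale": self.scale,
            "boundary_knots": [float(k) for k in self.boundary_knots],
            "internal_knots": [float(k) for k in self.internal_knots],
            "coeffs": [float(c) for c in self.coeffs],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
        }


def _neg_loglik(phi, basis_ev, dbasis_ev, basis_ce, x_ev, scale,
                dbasis_grid):
    eta_ev = basis_ev @ phi
    etap_ev = dbasis_ev @ phi
    pen = 0.0
    slopes = dbasis_grid @ phi
    neg = np.minimum(slopes, 0.0)
    pen = _BARRIER * float(neg @ neg)
    if np.any(etap_ev <= 0):
        # invalid density at an event time: push back with a large value
        return 1e8 + pen + float(np.sum(np.minimum(etap_ev, 0.0) ** 2))
    log_etap = np.log(etap_ev)
    if scale == "hazard":
        ll = np.sum(eta_ev - np.exp(eta_ev) + log_etap - x_ev)
        if basis_ce.size:
            ll += np.sum(-np.exp(basis_ce @ phi))
    elif scale == "odds":
        ll = np.sum(eta_ev - 2 * np.logaddexp(0.0, eta_ev) + log_etap - x_ev)
        if basis_ce.size:
            ll += np.sum(-np.logaddexp(0.0, basis_ce @ phi))
    else:
        ll = np.sum(_norm_logpdf(eta_ev) + log_etap - x_ev)
        if basis_ce.size:
            ll += np.sum(log_ndtr(-(basis_ce @ phi)))
    if not np.isfinite(ll):
        return 1e8 + pen
    return -ll + pen


def fit_rp(times, status, scale: str, n_internal_knots: int = 0,
           rng=None) -> SplineModel:
    """Fit a spline survival model by maximum likelihood.

    Parameters
    ----------
    times, status : observed follow-up times (> 0) and event indicators.
    scale : one of ``"hazard"``, ``"odds"``, ``"normal"``.
    n_internal_knots : number ``p`` of internal knots, placed at the
        quantiles ``j/(p+1)`` of the uncensored log times
        (linear-interpolation quantiles).
    rng : seed or generator for the jittered restarts used on
        non-convergence.

    Raises :class:`SplineFitError` on too few events, non-convergence, or a
    monotonicity violation of the fitted transformed survival curve.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    p = int(n_internal_knots)
    times = np.asarray(times, dtype=float)
    status = np.asarray(status).astype(bool)
    if np.any(times <= 0):
        keep = times > 0
        times, status = times[keep], status[keep]
    x_ev = np.log(times[status])
    if x_ev.size < p + 3 or np.unique(x_ev).size < p + 2:
        raise SplineFitError(
            f"too few uncensored times for p={p} on scale {scale!r}")
    kmin, kmax = float(x_ev.min()), float(x_ev.max())
    if kmax - kmin < 1e-10:
        raise SplineFitError("degenerate boundary knots")
    if p > 0:
        internal = tuple(np.quantile(x_ev, np.arange(1, p + 1) / (p + 1)))
        if np.any(np.diff((kmin,) + internal + (kmax,)) <= 0):
            raise SplineFitError("knots not strictly increasing")
    else:
        internal = ()
    bknots = (kmin, kmax)

    x_ce = np.log(times[~status]) if (~status).any() else np.empty(0)
    basis_ev = spline_basis(x_ev, internal, bknots)
    dbasis_ev = spline_basis_deriv(x_ev, internal, bknots)
    basis_ce = (spline_basis(x_ce, internal, bknots)
                if x_ce.size else np.empty((0, p + 2)))
    grid = np.linspace(kmin - _MONO_MARGIN, kmax + _MONO_MARGIN, 128)
    dbasis_grid = spline_basis_deriv(grid, internal, bknots)

    mu, sd = float(np.mean(x_ev)), float(np.std(x_ev))
    sd = max(sd, 1e-3)
    phi0 = np.zeros(p + 2)
    phi0[0], phi0[1] = -mu / sd, 1.0 / sd
    args = (basis_ev, dbasis_ev, basis_ce, x_ev, scale, dbasis_grid)

    rng = np.random.default_rng(rng)
    best = None
    for attempt in range(4):
        start = phi0 if attempt == 0 else phi0 + rng.normal(
            0, 0.2 * (1 + np.abs(phi0)))
        res = minimize(_neg_loglik, start, args=args, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12,
                                "gtol": 1e-8})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.fun < 1e7 and res.success:
            break
    if best is None or best.fun >= 1e7:
        raise SplineFitError(
            f"optimizer failed for p={p}, scale={scale!r}")

    phi = best.x
    fine = np.linspace(kmin - _MONO_MARGIN, kmax + _MONO_MARGIN, _MONO_GRID)
    if np.any(spline_basis_deriv(fine, internal, bknots) @ phi < -1e-8):
        raise SplineFitError(
            f"fitted transform not monotone for p={p}, scale={scale!r}")
    # penalty is ~0 at a valid optimum; recompute the clean log-likelihood
    loglik = -_neg_loglik(phi, basis_ev, dbasis_ev, basis_ce, x_ev, scale,
                          np.empty((0, p + 2)))
    n_par = p + 2
    return SplineModel(scale=scale, boundary_knots=bknots,
                       internal_knots=internal, coeffs=phi,
                       loglik=float(loglik),
                       aic=float(-2 * loglik + 2 * n_par))


def fit_grid(times, status, knot_counts: Sequence[int] = (0, 1, 2),
             scales: Sequence[str] = SCALES, rng=None) -> list:
    """Fit the candidate model grid, skipping failures with a warning."""
    models = []
    for scale in scales:
        for p in knot_counts:
            try:
                models.append(fit_rp(times, status, scale, p, rng=rng))
            except SplineFitError as err:
                warnings.warn(f"spline fit skipped: {err}")
    return models


def select_by_aic(models: Sequence[SplineModel]) -> SplineModel:
    """Minimum-AIC model; ties go to fewer knots, then hazard<odds<normal."""
    models = [m for m in models if m is not None]
    if not models:
        raise SplineFitError("no successfully fitted models to select from")
    return min(models, key=lambda m: (m.aic, len(m.internal_knots),
                                      _SCALE_ORDER[m.scale]))


def model_functions(model: SplineModel):
    """Convenience triple ``(survival, density, hazard)`` of callables."""
    return model.survival, model.density, model.hazard
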