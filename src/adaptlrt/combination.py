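"""Stage-wise p-value combination functions for two-stage designs.

A combination function ``C(p1, p2)`` is nondecreasing in both arguments
and continuous in ``p2``; under the p-clud property the final test
"reject iff C(p1, p2) <= c" controls the level when the bounds satisfy
the two-stage level condition.  The shipped combiners are the
inverse-normal rule

    C(p1, p2) = 1 - Phi(w1 z(p1) + w2 z(p2)),  z(p) = Phi^{-1}(1 - p)

with ``w1^2 + w2^2 = 1``, and Fisher's product ``C = p1 * p2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["Combiner", "InverseNormalCombiner", "FisherCombiner",
           "conditional_error"]

_PCLAMP = 1e-15


class Combiner:
    """Base interface: ``combine`` and (optionally) ``conditional_error``."""

    def combine(self, p1: float, p2: float) -> float:
        raise NotImplementedError

    def conditional_error(self, p1: float, c: float) -> float:
        """Largest u with C(p1, u) <= c, by root finding (generic)."""
        if self.combine(p1, 1.0) <= c:
            return 1.0
        if self.combine(p1, _PCLAMP) > c:
            return 0.0
        return float(brentq(lambda u: self.combine(p1, u) - c,
                            _PCLAMP, 1.0, xtol=1e-12))


def _z(p: float) -> float:
    return norm.isf(min(max(p, _PCLAMP), 1 - _PCLAMP))


@dataclass(frozen=True)
class InverseNormalCombiner(Combiner):
    """Inverse-normal combination with fixed stage weights."""

    w1: float = math.sqrt(0.5)
    w2: float = math.sqrt(0.5)

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("stage weights must be nonnegative")
        if abs(self.w1 ** 2 + self.w2 ** 2 - 1.0) > 1e-10:
            raise ValueError("stage weights must satisfy w1^2 + w2^2 = 1")

    def combine(self, p1: float, p2: float) -> float:
        return float(norm.sf(self.w1 * _z(p1) + self.w2 * _z(p2)))

    def conditional_error(self, p1: float, c: float) -> float:
        if self.w2 == 0:
            raise ValueError("stage 2 carries no weight (w2 = 0)")
        return float(norm.sf((_z(c) - self.w1 * _z(p1)) / self.w2))


@dataclass(frozen=True)
class FisherCombiner(Combiner):
    """Fisher product combination ``C(p1, p2) = p1 * p2``."""

    def combine(self, p1: float, p2: float) -> float:
        return float(p1 * p2)

    def conditional_error(self, p1: float, c: float) -> float:
        if p1 <= 0:
            return 1.0
        return float(min(1.0, c / p1))


def conditional_error(p1: float, combiner: Combiner, c: float) -> float:
    """Conditional error: the level available to stage 2 given ``p1``.

    Equals ``sup{u in [0,1]: C(p1, u) <= c}``; closed forms are used for
    the shipped combiners, root finding otherwise.
    """
    if not 0 < p1 <= 1:
        raise ValueError("p1 must lie in (0, 1]")
    return combiner.conditional_error(p1, c)
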