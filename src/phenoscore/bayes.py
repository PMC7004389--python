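"""The probability-update transformation and its group algebra.

A single experimental observation with true-positive rate τ and
false-positive rate ϕ updates a probability p via

    p' = τ·p / ((τ − ϕ)·p + ϕ)

which is exactly multiplication of the odds p/(1−p) by ω = τ/ϕ. Negative
evidence (a measurement performed but not supporting the feature) uses the
replacements τ → 1−τ and ϕ → 1−ϕ. Because every update is an odds
multiplication, the set of updates forms a commutative group: τ=ϕ is the
identity, swapping τ and ϕ gives the inverse, and composition is
order-invariant.

Accumulated evidence is represented internally as a log-odds sum and
converted to a probability only at read-out, so order invariance holds to
floating-point accuracy even over thousands of updates, and values near 0
and 1 stay well-conditioned. p = 0 and p = 1 are absorbing fixed points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "EPSILON",
    "UpdateFactor",
    "update_positive",
    "update_negative",
    "compose",
    "logit",
    "expit",
    "clamp",
]

#: Probabilities fed into odds computations are clamped to [EPSILON, 1-EPSILON]
#: to keep 0 and 1 from becoming absorbing through rounding alone.
EPSILON = 1e-12


def clamp(p: float, eps: float = EPSILON) -> float:
    """Clamp a probability into the open interval [eps, 1-eps]."""
    return min(max(p, eps), 1.0 - eps)


def logit(p: float) -> float:
    return math.log(p) - math.log1p(-p)


def expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class UpdateFactor:
    """One observation's (τ, ϕ) pair; ω = τ/ϕ is its odds factor.

    Both rates must lie strictly inside (0, 1): τ or ϕ of exactly 0 or 1
    describes a degenerate assay whose update is not invertible.
    """

    tau: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError(f"tau must be in (0,1), got {self.tau}")
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must be in (0,1), got {self.phi}")

    @property
    def omega(self) -> float:
        return self.tau / self.phi

    @property
    def log_omega(self) -> float:
        return math.log(self.tau) - math.log(self.phi)

    def inverse(self) -> "UpdateFactor":
        """The factor that undoes this one (τ and ϕ swapped)."""
        return UpdateFactor(self.phi, self.tau)

    def negated(self) -> "UpdateFactor":
        """The corresponding negative-evidence factor (1−τ, 1−ϕ)."""
        return UpdateFactor(1.0 - self.tau, 1.0 - self.phi)

    def is_identity(self, tol: float = 0.0) -> bool:
        return abs(self.tau - self.phi) <= tol


def update_positive(p: float, f: UpdateFactor) -> float:
    """Apply one positive observation: multiply the odds of ``p`` by ω."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {p}")
    if p == 0.0 or p == 1.0:
        return p
    if f.tau == f.phi:
        return p
    # interior inputs stay interior: rounding never reaches the absorbing ends
    return clamp(expit(logit(p) + f.log_omega))


def update_negative(p: float, f: UpdateFactor) -> float:
    """Apply one negative observation: the (1−τ, 1−ϕ) update."""
    return update_positive(p, f.negated())


def compose(p: float, factors: Iterable[UpdateFactor]) -> float:
    """Apply many positive updates at once via a single log-odds sum."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {p}")
    if p == 0.0 or p == 1.0:
        return p
    return clamp(expit(logit(p) + math.fsum(f.log_omega for f in factors)))
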