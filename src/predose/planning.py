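"""Measurement time-point planning from an effective half-life.

Two schedule generators are provided.  The empirical rule spreads ``n``
points over [Tmin, Tmax] with a power-1.5 progression:

    Ti   = Tmin + (Tmax - Tmin) * ((i - 1) / (n - 1))**1.5
    Tmin = Te / (n - 1)
    Tmax = 1.5 * n * Te / (0.15 * n + 1)

so early kinetics are sampled densely and the tail sparsely.  The ICRU
alternative uses the fixed multiples {1/3, 2/3, 3/2, 3, 5} of the effective
half-life Te.  Both schedules scale linearly in Te.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["Schedule", "plan_empirical", "plan_icru", "effective_half_life"]

_ICRU_MULTIPLES = (1.0 / 3.0, 2.0 / 3.0, 1.5, 3.0, 5.0)


@dataclass(frozen=True)
class Schedule:
    """A planned sequence of measurement times post-administration."""

    n: int
    te_h: float
    times_h: np.ndarray
    method: str  # "empirical" | "icru"

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        if t.size != self.n:
            raise ValidationError("schedule length must equal n")
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("schedule times must be positive and strictly increasing")
        object.__setattr__(self, "times_h", t)

    def __str__(self) -> str:
        shown = ", ".join(f"{t:.3g}" for t in self.times_h)
        return f"{self.method} schedule (Te = {self.te_h:g} h): {shown} h"


def plan_empirical(n: int, te_h: float) -> Schedule:
    """Plan ``n`` time points for a region with effective half-life ``te_h``."""
    if n < 2:
        raise ValidationError("the empirical rule needs at least 2 time points")
    if not te_h > 0:
        raise ValidationError("effective half-life must be positive")
    t_min = te_h / (n - 1)
    t_max = 1.5 * n * te_h / (0.15 * n + 1)
    i = np.arange(1, n + 1, dtype=float)
    times = t_min + (t_max - t_min) * ((i - 1) / (n - 1)) ** 1.5
    return Schedule(n=n, te_h=te_h, times_h=times, method="empirical")


def plan_icru(te_h: float) -> Schedule:
    """The five ICRU effective-half-life multiples: Te/3, 2Te/3, 3Te/2, 3Te, 5Te."""
    if not te_h > 0:
        raise ValidationError("effective half-life must be positive")
    times = te_h * np.array(_ICRU_MULTIPLES)
    return Schedule(n=5, te_h=te_h, times_h=times, method="icru")


def effective_half_life(lambda_b: float, lambda_p: float) -> float:
    """Te = ln 2 / (lambda_b + lambda_p), both rates in 1/h."""
    total = lambda_b + lambda_p
    if not total > 0:
        raise ValidationError("combined clearance rate must be positive")
    return math.log(2.0) / total
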