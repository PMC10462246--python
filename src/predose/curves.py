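"""Time-series containers shared by the biodistribution and transposition layers.

Two quantities travel through the pipeline and must never be confused:

* ``ConcentrationSeries`` carries mean SUV per time point.  SUV is
  decay-corrected to the time of administration by definition, and under the
  first-order cross-species assumption it is the quantity that transfers
  unchanged between an animal and a phantom.
* ``TimeActivitySeries`` carries a(rS, t), the fraction of the administered
  activity present in a phantom source region.  It is decay-UNcorrected —
  this is the integrand of the time-integrated activity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ConcentrationSeries", "TimeActivitySeries"]


def _as_sorted_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("time vector must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    return t


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-time-point mean SUV (with replicate scatter) for one region.

    Parameters
    ----------
    region : str
        Measured region label (assay-side name, before phantom mapping).
    times_h : array-like
        Times post-administration in hours, strictly increasing.
    suv_mean, suv_sd : array-like
        Mean and sample standard deviation of the per-animal SUVs at each
        time point.  SD is 0 wherever only one replicate exists.
    n : array-like of int
        Replicate count per time point.
    meta : dict
        Provenance flags, e.g. ``{"mean_mass_approximation": True}``.
    """

    region: str
    times_h: np.ndarray
    suv_mean: np.ndarray
    suv_sd: np.ndarray
    n: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = _as_sorted_times(self.times_h)
        mean = np.asarray(self.suv_mean, dtype=float)
        sd = np.asarray(self.suv_sd, dtype=float)
        n = np.asarray(self.n, dtype=int)
        if not (t.shape == mean.shape == sd.shape == n.shape):
            raise ValidationError("times, means, SDs and counts must align")
        if np.any(mean < 0):
            raise ValidationError("mean SUV must be non-negative")
        if np.any(sd < 0):
            raise ValidationError("SUV SD must be non-negative")
        if np.any(n < 1):
            raise ValidationError("each time point needs at least one replicate")
        if np.any(sd[n == 1] != 0):
            raise ValidationError("SD must be 0 at single-replicate time points")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "suv_mean", mean)
        object.__setattr__(self, "suv_sd", sd)
        object.__setattr__(self, "n", n)

    def __len__(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class TimeActivitySeries:
    """Decay-uncorrected fraction of administered activity a(rS, t).

    ``values`` are dimensionless fractions of the administered activity in
    the phantom source region ``region`` at ``times_h`` post-administration,
    with physical decay included (no decay correction).  ``sd`` carries the
    propagated replicate scatter on the same scale.
    """

    region: str
    times_h: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self):
        t = _as_sorted_times(self.times_h)
        a = np.asarray(self.values, dtype=float)
        if a.shape != t.shape:
            raise ValidationError("times and values must align")
        if np.any(a < 0):
            raise ValidationError("activity fractions must be non-negative")
        sd = self.sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != t.shape or np.any(sd < 0):
                raise ValidationError("SD vector must align and be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", a)
        object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return self.times_h.size
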