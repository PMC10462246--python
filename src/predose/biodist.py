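"""Raw biodistribution measurements and their reduction to SUV series.

The standardized uptake value (SUV) used throughout is the activity mass
concentration decay-corrected to the time of administration, normalized to
the activity administered per unit body mass:

    SUV = (%IA/g) * M_body / 100

where %IA/g is the percent of administered activity per gram of tissue.
Volume concentrations (%IA/mL, typical for tomographic images) are divided
by tissue density to obtain mass concentration first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import ConcentrationSeries, TimeActivitySeries
from .errors import FormatError, ValidationError
from .refdata import TOTAL_BODY, Phantom

__all__ = [
    "Measurement",
    "WholeBodyRatioSeries",
    "suv_from_pct_ia_per_g",
    "pct_ia_per_g_from_suv",
    "concentration_from_volume",
    "aggregate",
    "total_body_from_carcass",
    "total_body_from_ratios",
    "load_biodist",
    "load_wholebody_ratios",
]

_UNITS = ("pct_ia_per_g", "suv", "pct_ia_per_ml")


def suv_from_pct_ia_per_g(pct: float, body_mass_g: float) -> float:
    """SUV from %IA/g and the subject's total-body mass in grams."""
    if pct < 0:
        raise ValidationError("%IA/g must be non-negative")
    if not body_mass_g > 0:
        raise ValidationError("body mass must be positive")
    return pct * body_mass_g / 100.0


def pct_ia_per_g_from_suv(suv: float, body_mass_g: float) -> float:
    """Exact inverse of :func:`suv_from_pct_ia_per_g`."""
    if suv < 0:
        raise ValidationError("SUV must be non-negative")
    if not body_mass_g > 0:
        raise ValidationError("body mass must be positive")
    return suv * 100.0 / body_mass_g


def concentration_from_volume(pct_ia_per_ml: float, density_g_per_ml: float = 1.0) -> float:
    """Convert %IA/mL to %IA/g by dividing by tissue density (default 1 g/mL)."""
    if pct_ia_per_ml < 0:
        raise ValidationError("%IA/mL must be non-negative")
    if not density_g_per_ml > 0:
        raise ValidationError("tissue density must be positive")
    return pct_ia_per_ml / density_g_per_ml


@dataclass(frozen=True)
class Measurement:
    """One decay-corrected activity-concentration reading for one animal.

    %IA/g and SUV are decay-corrected to the time of administration by
    definition; readings in these units must be entered decay-corrected.
    """

    region: str
    time_h: float
    replicate: str
    value: float
    unit: str
    body_mass_g: float
    density_g_per_ml: float = 1.0

    def __post_init__(self):
        if self.time_h < 0:
            raise ValidationError("time post-administration must be >= 0")
        if self.value < 0:
            raise ValidationError("concentration must be non-negative")
        if not self.body_mass_g > 0:
            raise ValidationError("animal body mass must be positive")
        if self.unit not in _UNITS:
            raise ValidationError(f"unit must be one of {_UNITS}, got {self.unit!r}")

    def suv(self, body_mass_g: float | None = None) -> float:
        """This reading as SUV, using the animal's own mass unless overridden."""
        mass = self.body_mass_g if body_mass_g is None else body_mass_g
        if self.unit == "suv":
            return self.value
        pct = self.value
        if self.unit == "pct_ia_per_ml":
            pct = concentration_from_volume(pct, self.density_g_per_ml)
        return suv_from_pct_ia_per_g(pct, mass)


def aggregate(
    measurements: list[Measurement],
    use_population_mean_mass: bool = False,
) -> ConcentrationSeries:
    """Reduce per-animal measurements of one region to a mean-SUV series.

    By default each animal's SUV is computed with its own body mass before
    averaging.  ``use_population_mean_mass=True`` instead applies the
    population mean body mass to the mean concentration — the common
    shortcut when body masses are nearly uniform — and flags the output.
    The per-time-point SD is the sample standard deviation (n-1).
    """
    if not measurements:
        raise ValidationError("no measurements to aggregate")
    regions = {m.region for m in measurements}
    if len(regions) > 1:
        raise ValidationError(f"mixed regions in one aggregation: {sorted(regions)}")
    mean_mass = float(np.mean([m.body_mass_g for m in measurements]))
    by_time: dict[float, list[Measurement]] = {}
    for m in measurements:
        by_time.setdefault(m.time_h, []).append(m)
    times = sorted(by_time)
    means, sds, counts = [], [], []
    for t in times:
        if use_population_mean_mass:
            suvs = np.array([m.suv(body_mass_g=mean_mass) for m in by_time[t]])
        else:
            suvs = np.array([m.suv() for m in by_time[t]])
        means.append(suvs.mean())
        sds.append(suvs.std(ddof=1) if suvs.size > 1 else 0.0)
        counts.append(suvs.size)
    return ConcentrationSeries(
        region=measurements[0].region,
        times_h=np.array(times),
        suv_mean=np.array(means),
        suv_sd=np.array(sds),
        n=np.array(counts),
        meta={
            "mean_mass_approximation": use_population_mean_mass,
            "population_mean_body_mass_g": mean_mass,
        },
    )


def total_body_from_carcass(
    carcass: ConcentrationSeries,
    excised: list[ConcentrationSeries],
    phantom: Phantom,
    carcass_region: str = "Carcass",
    mass_closure_rtol: float = 0.005,
) -> ConcentrationSeries:
    """Total-body SUV series from a carcass series plus excised-organ series.

    The whole-body concentration is the mass-weighted mean of the carcass and
    the organs removed from it, with every mass taken from the phantom:

        SUV_TB = (SUV_carcass * M_carcass + sum_r SUV_r * M_r) / M_TB

    Each excised region may appear once (an organ partially left in the
    carcass would be double-counted).  If the carcass plus excised masses do
    not close on the total-body mass within ``mass_closure_rtol`` a warning
    is emitted.
    """
    names = [s.region for s in excised]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValidationError(f"excised regions listed more than once: {dupes}")
    times = carcass.times_h
    for s in excised:
        if not np.array_equal(s.times_h, times):
            raise ValidationError(f"time grid of {s.region!r} differs from the carcass grid")
    m_tb = phantom.total_body_mass_g
    m_carcass = phantom.mass(carcass_region)
    m_exc = {s.region: phantom.mass(s.region) for s in excised}
    closure = m_carcass + sum(m_exc.values())
    if abs(closure - m_tb) > mass_closure_rtol * m_tb:
        warnings.warn(
            f"carcass + excised masses = {closure} g vs total body {m_tb} g "
            f"(> {mass_closure_rtol:.1%} apart)",
            stacklevel=2,
        )
    total = carcass.suv_mean * m_carcass
    var = (carcass.suv_sd * m_carcass) ** 2
    for s in excised:
        total = total + s.suv_mean * m_exc[s.region]
        var = var + (s.suv_sd * m_exc[s.region]) ** 2
    n = np.minimum.reduce([carcass.n] + [s.n for s in excised])
    sd = np.sqrt(var) / m_tb
    sd[n == 1] = 0.0
    return ConcentrationSeries(
        region="Totalbody",
        times_h=times,
        suv_mean=total / m_tb,
        suv_sd=sd,
        n=n,
        meta={"composed_from": [carcass_region, *names]},
    )


@dataclass(frozen=True)
class WholeBodyRatioSeries:
    """Raw dose-calibrator readings A(Ti)/A(T0); NOT decay-corrected.

    The reading at the time of administration defines 100% of the
    administered activity, so the ratio series is directly the fraction of
    administered activity remaining in the body.
    """

    times_h: np.ndarray
    ratios: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        if t.size == 0:
            raise ValidationError("empty whole-body ratio series")
        if t.shape != r.shape or t.ndim != 1:
            raise ValidationError("times and ratios must be aligned 1-D vectors")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if t[0] != 0:
            raise ValidationError("a T0 (time-of-administration) reading is required")
        if r[0] != 1.0:
            raise ValidationError("the ratio at T0 must be 1 by construction")
        if np.any(r < 0):
            raise ValidationError("ratios must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "ratios", r)


def total_body_from_ratios(ratios: WholeBodyRatioSeries) -> TimeActivitySeries:
    """Total-body activity fractions straight from dose-calibrator ratios.

    The readings are not decay-corrected, so the ratios are used directly as
    decay-uncorrected fractions — no further decay factor is applied.
    Ratios above 1 after administration are physically inconsistent; they
    are retained with a warning.
    """
    if np.any(ratios.ratios[1:] > 1.0):
        bad = ratios.times_h[1:][ratios.ratios[1:] > 1.0]
        warnings.warn(
            f"whole-body ratio > 1 at t = {bad.tolist()} h; reading retained "
            "but physically inconsistent",
            stacklevel=2,
        )
    return TimeActivitySeries(
        region="Totalbody",
        times_h=ratios.times_h,
        values=ratios.ratios,
        sd=None,
        provenance="dose-calibrator whole-body ratios",
    )


def measurements_from_frame(df: pd.DataFrame) -> list[Measurement]:
    """Build measurements from a biodistribution table (``biodist.csv`` layout)."""
    required = {"region", "time_h", "replicate", "value", "unit", "body_mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"biodistribution table: missing column(s) {sorted(missing)}")
    return [
        Measurement(
            region=str(r.region),
            time_h=float(r.time_h),
            replicate=str(r.replicate),
            value=float(r.value),
            unit=str(r.unit),
            body_mass_g=float(r.body_mass_g),
            density_g_per_ml=float(getattr(r, "density_g_per_ml", 1.0)),
        )
        for r in df.itertuples()
    ]


def aggregate_by_region(
    measurements: list[Measurement], use_population_mean_mass: bool = False
) -> dict[str, ConcentrationSeries]:
    """Aggregate a mixed-region measurement list into one series per region."""
    by_region: dict[str, list[Measurement]] = {}
    for m in measurements:
        by_region.setdefault(m.region, []).append(m)
    return {
        region: aggregate(group, use_population_mean_mass=use_population_mean_mass)
        for region, group in by_region.items()
    }


def load_biodist(path) -> list[Measurement]:
    """Read ``biodist.csv``: region, time_h, replicate, value, unit, body_mass_g."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return measurements_from_frame(pd.read_csv(path, comment="#"))


def load_wholebody_ratios(path) -> WholeBodyRatioSeries:
    """Read ``wholebody_ratios.csv``: columns time_h, reading."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    missing = {"time_h", "reading"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    df = df.sort_values("time_h")
    t = df["time_h"].to_numpy(dtype=float)
    reading = df["reading"].to_numpy(dtype=float)
    if t.size == 0 or t[0] != 0:
        raise ValidationError(f"{path}: a reading at time 0 is required")
    return WholeBodyRatioSeries(times_h=t, ratios=reading / reading[0])
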