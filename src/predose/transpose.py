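"""Transposition of measured SUV curves onto phantom source regions.

Under the first-order assumption that SUV is equivalent across species and
between subjects and the phantoms representing them, the decay-uncorrected
fraction of administered activity in a phantom source region is

    a(rS, Ti) = SUV(rS, Ti) * M(rS) / M(Totalbody) * exp(-lambda_p * Ti)

with both masses taken from the phantom.  The exponential undoes the decay
correction baked into the SUV definition.  The same formula serves
same-species work (mouse data on a mouse phantom) and cross-species
extrapolation (mouse data on a human phantom).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import ConcentrationSeries, TimeActivitySeries
from .errors import FormatError, ValidationError
from .refdata import Phantom, Radionuclide

__all__ = [
    "transpose_region",
    "red_marrow_from_blood",
    "total_body_fraction",
    "check_activity_closure",
    "load_region_map",
]


def _scale_series(
    series: ConcentrationSeries,
    region: str,
    mass_ratio: float,
    nuclide: Radionuclide,
    provenance: str,
) -> TimeActivitySeries:
    decay = np.exp(-nuclide.lambda_p * series.times_h)
    return TimeActivitySeries(
        region=region,
        times_h=series.times_h,
        values=series.suv_mean * mass_ratio * decay,
        sd=series.suv_sd * mass_ratio * decay,
        provenance=provenance,
    )


def transpose_region(
    series: ConcentrationSeries,
    phantom: Phantom,
    nuclide: Radionuclide,
    target_region: str | None = None,
) -> TimeActivitySeries:
    """Map a measured SUV series onto a source-capable phantom region.

    ``target_region`` defaults to the measured region's own name; pass the
    phantom-side name when assay labels differ (see :func:`load_region_map`).
    Replicate SDs are scaled by the same mass ratio and decay factor.
    """
    region = series.region if target_region is None else target_region
    if region not in phantom.regions:
        raise ValidationError(f"phantom {phantom.name!r} has no region {region!r}")
    if region not in phantom.source_regions:
        raise ValidationError(f"region {region!r} is not source-capable in {phantom.name!r}")
    ratio = phantom.mass(region) / phantom.total_body_mass_g
    return _scale_series(
        series, region, ratio, nuclide, provenance=f"{series.region} -> {region}"
    )


def red_marrow_from_blood(
    blood: ConcentrationSeries,
    phantom: Phantom,
    nuclide: Radionuclide,
    marrow_region: str = "Redmarrow",
) -> TimeActivitySeries:
    """Red-marrow activity from the blood curve (blood-surrogate assumption).

    Pure red marrow cannot be harvested from small animals, so its activity
    concentration is taken equal to that of blood — conservative for agents
    that do not specifically bind marrow components.  The blood SUV is scaled
    by the phantom red-marrow mass.
    """
    if marrow_region not in phantom.regions:
        raise ValidationError(f"phantom {phantom.name!r} defines no red-marrow region")
    ratio = phantom.mass(marrow_region) / phantom.total_body_mass_g
    return _scale_series(
        blood,
        marrow_region,
        ratio,
        nuclide,
        provenance=f"{blood.region} (blood surrogate) -> {marrow_region}",
    )


def total_body_fraction(
    series: ConcentrationSeries, nuclide: Radionuclide
) -> TimeActivitySeries:
    """Decay-uncorrected whole-body fraction from a total-body SUV series.

    The total-body SUV already equals the fraction of administered activity
    (decay-corrected), so no mass ratio is needed — only the decay factor.
    """
    return _scale_series(
        series, "Totalbody", 1.0, nuclide, provenance=f"{series.region} -> Totalbody"
    )


def check_activity_closure(
    series_list: list[TimeActivitySeries], tolerance_sds: float = 2.0
) -> bool:
    """Audit that disjoint source regions never hold more than the administered activity.

    At every time shared by all series, the summed fractions must satisfy
    sum(a) <= 1 + ``tolerance_sds`` * propagated SD.  Violations are reported
    by warning (measurement noise makes this a soft check); returns True
    when the audit passes.
    """
    if not series_list:
        return True
    shared = set(series_list[0].times_h.tolist())
    for s in series_list[1:]:
        shared &= set(s.times_h.tolist())
    ok = True
    for t in sorted(shared):
        total, var = 0.0, 0.0
        for s in series_list:
            i = int(np.searchsorted(s.times_h, t))
            total += s.values[i]
            if s.sd is not None:
                var += s.sd[i] ** 2
        if total > 1.0 + tolerance_sds * np.sqrt(var) + 1e-12:
            warnings.warn(
                f"activity closure violated at t = {t} h: sum a = {total:.4g} "
                f"over regions {[s.region for s in series_list]}",
                stacklevel=2,
            )
            ok = False
    return ok


def load_region_map(path) -> dict[str, str]:
    """Read ``region_map.csv`` (columns measured_region, phantom_region).

    The mapping is explicit and user-edited; no fuzzy name matching is ever
    attempted.  Measured regions without a phantom counterpart should be
    left out of the map — their activity stays in the rest of body.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    missing = {"measured_region", "phantom_region"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return {str(r.measured_region): str(r.phantom_region) for r in df.itertuples()}
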