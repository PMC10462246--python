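"""Dose coefficients from TIACs and S-values.

The absorbed dose coefficient of a target region is the S-value-weighted
sum over source regions,

    d(rT) = sum_rS  a~(rS) * S(rT <- rS)

with TIACs in hours and S-values in Gy/(Bq·s); the single hours-to-seconds
conversion of the pipeline happens here.  On top of the absorbed dose the
module applies radiation weighting (equivalent dose, wR), tissue weighting
with sex averaging (effective dose, wT — defined for reference humans
only), and RBE weighting for deterministic endpoints, plus the
local-absorption self-dose sanity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError
from .refdata import Phantom, Radionuclide, SValueMatrix, TissueWeightingTable
from .tiac import TIACResult

__all__ = [
    "DoseReport",
    "absorbed_dose",
    "equivalent_dose",
    "effective_dose",
    "rbe_weighted_dose",
    "self_dose_check",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class DoseReport:
    """Per-target dose coefficients with their per-source breakdown.

    ``absorbed_Gy_per_Bq[target]`` is the absorbed dose coefficient;
    ``contributions[target][source]`` its additive per-source breakdown;
    ``by_radiation[rtype][target]`` the partition over radiation types when
    one is available (needed for wR/RBE weighting); ``equivalent_Sv_per_Bq``
    is populated by :func:`equivalent_dose` and ``weighted`` by
    :func:`rbe_weighted_dose` (unit label in ``weighted_unit``).
    """

    phantom_name: str
    nuclide_name: str
    species_label: str = ""
    absorbed_Gy_per_Bq: dict[str, float] = field(default_factory=dict)
    contributions: dict[str, dict[str, float]] = field(default_factory=dict)
    by_radiation: dict[str, dict[str, float]] | None = None
    equivalent_Sv_per_Bq: dict[str, float] | None = None
    weighted: dict[str, float] | None = None
    weighted_unit: str = "Gy-Eq"

    def __post_init__(self):
        for target, d in self.absorbed_Gy_per_Bq.items():
            if d < 0:
                raise ValidationError(f"negative dose coefficient for {target!r}")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(self.absorbed_Gy_per_Bq)

    @property
    def is_human(self) -> bool:
        return "human" in self.species_label.lower()


def absorbed_dose(
    tiacs: list[TIACResult],
    svalues: SValueMatrix,
    phantom: Phantom | None = None,
    nuclide: Radionuclide | None = None,
) -> DoseReport:
    """Absorbed dose coefficients [Gy/Bq] for every target in the S-matrix.

    Every TIAC region must exist as a source in the S-value matrix (a TIAC
    with no S column would silently vanish from the dose — an error).  When
    the S-matrix carries a per-radiation-type breakdown it is propagated;
    otherwise, if the nuclide declares dose fractions per radiation type,
    the total is partitioned by those fractions.
    """
    sources = set(svalues.sources)
    seen: set[str] = set()
    for res in tiacs:
        if res.region in seen:
            raise ValidationError(f"duplicate TIAC for region {res.region!r}")
        seen.add(res.region)
        if res.region not in sources:
            raise ValidationError(
                f"TIAC provided for {res.region!r} but the S-value matrix has "
                "no such source region"
            )
    targets = (
        sorted(phantom.target_regions) if phantom is not None else list(svalues.regions)
    )
    absorbed: dict[str, float] = {}
    contributions: dict[str, dict[str, float]] = {}
    rtypes = svalues.radiation_types
    by_radiation: dict[str, dict[str, float]] | None = {t: {} for t in rtypes} or None
    for target in targets:
        per_source = {
            res.region: res.tiac_h * SECONDS_PER_HOUR * svalues.s(target, res.region)
            for res in tiacs
        }
        contributions[target] = per_source
        absorbed[target] = sum(per_source.values())
        if by_radiation is not None:
            for rtype in rtypes:
                by_radiation[rtype][target] = sum(
                    res.tiac_h * SECONDS_PER_HOUR * svalues.s(target, res.region, rtype)
                    for res in tiacs
                )
    if by_radiation is None and nuclide is not None and nuclide.radiation_fractions:
        by_radiation = {
            rtype: {t: frac * absorbed[t] for t in absorbed}
            for rtype, frac in nuclide.radiation_fractions.items()
        }
    return DoseReport(
        phantom_name=svalues.phantom_name,
        nuclide_name=svalues.nuclide_name or (nuclide.name if nuclide else ""),
        species_label=phantom.species_label if phantom is not None else "",
        absorbed_Gy_per_Bq=absorbed,
        contributions=contributions,
        by_radiation=by_radiation,
    )


def _require_breakdown(report: DoseReport) -> dict[str, dict[str, float]]:
    if not report.by_radiation:
        raise ValidationError(
            "per-radiation-type dose breakdown unavailable: supply per-type "
            "S-values or nuclide dose fractions"
        )
    return report.by_radiation


def equivalent_dose(report: DoseReport, weights: TissueWeightingTable) -> DoseReport:
    """Apply radiation weighting factors: h(rT) = sum_R wR * d_R(rT) [Sv/Bq].

    Radiation types missing from the wR table default to wR = 1 (photons,
    electrons, betas).
    """
    breakdown = _require_breakdown(report)
    equivalent = {
        target: sum(
            weights.radiation.get(rtype, 1.0) * per_target[target]
            for rtype, per_target in breakdown.items()
        )
        for target in report.targets
    }
    return DoseReport(
        phantom_name=report.phantom_name,
        nuclide_name=report.nuclide_name,
        species_label=report.species_label,
        absorbed_Gy_per_Bq=report.absorbed_Gy_per_Bq,
        contributions=report.contributions,
        by_radiation=report.by_radiation,
        equivalent_Sv_per_Bq=equivalent,
        weighted=report.weighted,
        weighted_unit=report.weighted_unit,
    )


def effective_dose(
    male: DoseReport,
    female: DoseReport,
    weights: TissueWeightingTable,
) -> tuple[float, dict[str, float]]:
    """Sex-averaged, tissue-weighted effective dose coefficient [Sv/Bq].

        e = sum_T wT * (h_T(male) + h_T(female)) / 2

    Returns the scalar plus the per-tissue contribution table.  Effective
    dose is a stochastic-risk metric defined for reference humans; animal
    phantoms are refused.
    """
    for report in (male, female):
        if not report.is_human:
            raise ValidationError(
                "effective dose is defined for reference human phantoms only; "
                f"got species {report.species_label!r} — report absorbed or "
                "RBE-weighted dose instead"
            )
        if report.equivalent_Sv_per_Bq is None:
            raise ValidationError("effective dose needs equivalent-dose reports")
    contributions: dict[str, float] = {}
    for tissue, w_t in weights.tissue.items():
        for report, label in ((male, "male"), (female, "female")):
            if tissue not in report.equivalent_Sv_per_Bq:
                raise ValidationError(
                    f"tissue {tissue!r} is weighted but absent from the {label} report"
                )
        contributions[tissue] = (
            w_t
            * (male.equivalent_Sv_per_Bq[tissue] + female.equivalent_Sv_per_Bq[tissue])
            / 2.0
        )
    return sum(contributions.values()), contributions


def rbe_weighted_dose(
    report: DoseReport, rbe: dict[str, float], unit_label: str = "Gy-Eq"
) -> DoseReport:
    """RBE-weighted dose for deterministic endpoints: sum_R RBE_R * d_R(rT).

    There is no consensus unit for RBE-weighted dose; pick the label
    (``Gy``, ``Gy-Eq`` or ``Sv``) that matches local reporting convention.
    Radiation types missing from ``rbe`` default to 1.
    """
    for rtype, factor in rbe.items():
        if not factor > 0:
            raise ValidationError(f"RBE for {rtype!r} must be positive")
    breakdown = _require_breakdown(report)
    weighted = {
        target: sum(
            rbe.get(rtype, 1.0) * per_target[target]
            for rtype, per_target in breakdown.items()
        )
        for target in report.targets
    }
    return DoseReport(
        phantom_name=report.phantom_name,
        nuclide_name=report.nuclide_name,
        species_label=report.species_label,
        absorbed_Gy_per_Bq=report.absorbed_Gy_per_Bq,
        contributions=report.contributions,
        by_radiation=report.by_radiation,
        equivalent_Sv_per_Bq=report.equivalent_Sv_per_Bq,
        weighted=weighted,
        weighted_unit=unit_label,
    )


def self_dose_check(
    tiac: TIACResult,
    region_mass_g: float,
    nuclide: Radionuclide,
    reported_d_Gy_per_Bq: float | None = None,
) -> dict:
    """Local-absorption sanity check of a region's self dose.

    Assuming the dominant dose contribution is complete local absorption of
    non-penetrating (particulate) emissions,

        d_approx = a~ [s] * Delta_np [J] / M [kg]

    The result is compared against the software-reported coefficient; a
    ratio further than half a decade from 1 is flagged.  For a pure-photon
    emitter (Delta_np = 0) the check is skipped.
    """
    if not region_mass_g > 0:
        raise ValidationError("region mass must be positive")
    if nuclide.delta_np_J == 0.0:
        return {
            "region": tiac.region,
            "d_approx_Gy_per_Bq": 0.0,
            "ratio": None,
            "flagged": False,
            "skipped": "pure-photon emitter (Delta_np = 0): no local-absorption check",
        }
    d_approx = tiac.tiac_h * SECONDS_PER_HOUR * nuclide.delta_np_J / (region_mass_g / 1000.0)
    ratio = None
    flagged = False
    if reported_d_Gy_per_Bq is not None and reported_d_Gy_per_Bq > 0:
        ratio = d_approx / reported_d_Gy_per_Bq
        flagged = abs(math.log10(ratio)) > 0.5
    return {
        "region": tiac.region,
        "d_approx_Gy_per_Bq": d_approx,
        "ratio": ratio,
        "flagged": flagged,
    }
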