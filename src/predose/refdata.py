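"""Reference data: phantoms, radionuclides, S-value matrices, weighting factors.

All on-disk formats are comma-delimited UTF-8 with one header row; lines
starting with ``#`` are comments.  Units on disk: masses in grams, half-lives
in hours, S-values in Gy/(Bq·s), mean non-penetrating energy per decay in
joules.  These files are meant to be exported from (or hand-built to match)
whatever organ-level dosimetry software supplies the S-values; the package
ships no reference phantom or S-value library of its own.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Phantom",
    "Radionuclide",
    "SValueMatrix",
    "TissueWeightingTable",
    "load_phantom",
    "write_phantom",
    "load_svalues",
    "load_nuclide",
    "load_weights",
    "TOTAL_BODY",
]

#: Reserved row label for the whole-body mass in phantom files.
TOTAL_BODY = "TOTALBODY"


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # malformed delimiter/quoting
        raise FormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


@dataclass(frozen=True)
class Phantom:
    """A named anatomical model: region masses plus total-body mass.

    Region masses are understood to be inclusive of the blood they contain,
    matching how harvested tissue samples are assayed.
    """

    name: str
    species_label: str
    total_body_mass_g: float
    regions: dict[str, float]
    source_regions: frozenset[str] = field(default_factory=frozenset)
    target_regions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.total_body_mass_g > 0:
            raise ValidationError("total-body mass must be positive")
        for region, mass in self.regions.items():
            if not mass > 0:
                raise ValidationError(f"region {region!r}: mass must be positive")
            if mass >= self.total_body_mass_g:
                raise ValidationError(
                    f"region {region!r}: mass {mass} g is not below the "
                    f"total-body mass {self.total_body_mass_g} g"
                )
        unknown = (self.source_regions | self.target_regions) - set(self.regions)
        if unknown:
            raise ValidationError(f"role flags reference unknown regions {sorted(unknown)}")

    def mass(self, region: str) -> float:
        """Mass of ``region`` in grams (``TOTALBODY`` gives the body mass)."""
        if region == TOTAL_BODY:
            return self.total_body_mass_g
        try:
            return self.regions[region]
        except KeyError:
            raise ValidationError(f"phantom {self.name!r} has no region {region!r}") from None

    @property
    def is_human(self) -> bool:
        return "human" in self.species_label.lower()


def load_phantom(path) -> Phantom:
    """Load a phantom definition from ``phantom.csv``.

    Expected columns: ``region, mass_g, is_source, is_target`` with one
    reserved ``TOTALBODY`` row carrying the whole-body mass.  An optional
    ``species`` column (constant) labels the species; the phantom name is
    the file stem.
    """
    path = Path(path)
    df = _read_csv(path, {"region", "mass_g", "is_source", "is_target"})
    dupes = df["region"][df["region"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate region rows {sorted(set(dupes))}")
    body = df[df["region"] == TOTAL_BODY]
    if len(body) != 1:
        raise FormatError(f"{path}: exactly one {TOTAL_BODY} row is required")
    organs = df[df["region"] != TOTAL_BODY]
    species = str(df["species"].iloc[0]) if "species" in df.columns else ""
    return Phantom(
        name=path.stem,
        species_label=species,
        total_body_mass_g=float(body["mass_g"].iloc[0]),
        regions={str(r.region): float(r.mass_g) for r in organs.itertuples()},
        source_regions=frozenset(str(r.region) for r in organs.itertuples() if int(r.is_source)),
        target_regions=frozenset(str(r.region) for r in organs.itertuples() if int(r.is_target)),
    )


def write_phantom(phantom: Phantom, path) -> None:
    """Write ``phantom`` back to CSV; numeric fields round-trip bit-exactly."""
    rows = [
        {
            "region": region,
            "mass_g": repr(mass),
            "is_source": int(region in phantom.source_regions),
            "is_target": int(region in phantom.target_regions),
            "species": phantom.species_label,
        }
        for region, mass in phantom.regions.items()
    ]
    rows.append(
        {
            "region": TOTAL_BODY,
            "mass_g": repr(phantom.total_body_mass_g),
            "is_source": 0,
            "is_target": 0,
            "species": phantom.species_label,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class Radionuclide:
    """Physical decay data for one radionuclide.

    ``radiation_fractions`` partitions the absorbed dose per decay among
    radiation-type labels (e.g. ``{"alpha": 0.9, "photon": 0.1}``); it feeds
    radiation-weighting (wR) and RBE-weighting of dose coefficients and may
    be empty when only unweighted absorbed dose is wanted.
    """

    name: str
    half_life_h: float
    delta_np_J: float = 0.0
    radiation_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.half_life_h > 0:
            raise ValidationError("physical half-life must be positive")
        if self.delta_np_J < 0:
            raise ValidationError("mean non-penetrating energy must be >= 0")
        for label, frac in self.radiation_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"dose fraction for {label!r} must lie in [0, 1]")

    @property
    def lambda_p(self) -> float:
        """Physical decay constant, 1/h."""
        return math.log(2.0) / self.half_life_h


def load_nuclide(path, name: str | None = None) -> Radionuclide:
    """Load decay data from ``nuclide.csv``.

    Columns: ``name, half_life_h, delta_np_J, radiation_type, dose_fraction``;
    one row per radiation type (half-life and delta repeated).  With several
    nuclides in one file, pass ``name`` to select one.
    """
    df = _read_csv(path, {"name", "half_life_h", "delta_np_J"})
    if name is not None:
        df = df[df["name"] == name]
        if df.empty:
            raise ValidationError(f"{path}: no rows for nuclide {name!r}")
    names = df["name"].unique()
    if len(names) != 1:
        raise ValidationError(f"{path}: ambiguous nuclide, found {sorted(names)}; pass name=")
    fractions: dict[str, float] = {}
    if "radiation_type" in df.columns and "dose_fraction" in df.columns:
        for row in df.itertuples():
            rtype = row.radiation_type
            if pd.isna(rtype):
                continue
            fractions[str(rtype)] = fractions.get(str(rtype), 0.0) + float(row.dose_fraction)
    return Radionuclide(
        name=str(names[0]),
        half_life_h=float(df["half_life_h"].iloc[0]),
        delta_np_J=float(df["delta_np_J"].iloc[0]),
        radiation_fractions=fractions,
    )


@dataclass(frozen=True)
class SValueMatrix:
    """S(rT ← rS) in Gy/(Bq·s) for one phantom + radionuclide.

    ``entries`` maps radiation-type label -> {(target, source): S}; the
    ``"total"`` type always exists and is the sum over types when the file
    carries a per-type breakdown.  Cross-fire pairs absent from the file
    read as 0 (a warning was emitted at load time); self-dose (diagonal)
    entries are mandatory for every source-capable phantom region because
    self-dose dominates organ dose for most radiopharmaceuticals.
    """

    phantom_name: str
    nuclide_name: str
    regions: tuple[str, ...]
    entries: dict[str, dict[tuple[str, str], float]]

    @property
    def radiation_types(self) -> tuple[str, ...]:
        return tuple(t for t in self.entries if t != "total")

    @property
    def sources(self) -> tuple[str, ...]:
        """Regions usable as sources: those with a self-dose column."""
        diag = self.entries["total"]
        return tuple(r for r in self.regions if (r, r) in diag)

    def s(self, target: str, source: str, radiation_type: str = "total") -> float:
        """S-value for (target ← source), 0 for an undeclared cross pair."""
        if target not in self.regions or source not in self.regions:
            raise ValidationError(
                f"({target!r} <- {source!r}) outside declared regions of "
                f"S-matrix for {self.phantom_name!r}"
            )
        try:
            table = self.entries[radiation_type]
        except KeyError:
            raise ValidationError(f"no S-values for radiation type {radiation_type!r}") from None
        return table.get((target, source), 0.0)


def load_svalues(path, phantom: Phantom, nuclide_name: str = "") -> SValueMatrix:
    """Load an S-value table from ``svalues.csv`` and check it against ``phantom``.

    Columns: ``target, source, svalue_Gy_per_Bq_s[, radiation_type]``; the
    radiation type defaults to ``"total"``.
    """
    path = Path(path)
    df = _read_csv(path, {"target", "source", "svalue_Gy_per_Bq_s"})
    known = set(phantom.regions)
    entries: dict[str, dict[tuple[str, str], float]] = {}
    for i, row in enumerate(df.itertuples(), start=2):
        target, source = str(row.target), str(row.source)
        for region in (target, source):
            if region not in known:
                raise ValidationError(
                    f"{path} row {i}: region {region!r} not defined in phantom "
                    f"{phantom.name!r}"
                )
        value = float(row.svalue_Gy_per_Bq_s)
        if value < 0:
            raise ValidationError(f"{path} row {i}: negative S-value {value}")
        rtype = "total"
        if hasattr(row, "radiation_type") and not pd.isna(row.radiation_type):
            rtype = str(row.radiation_type)
        entries.setdefault(rtype, {})[(target, source)] = value

    if "total" not in entries:
        totals: dict[tuple[str, str], float] = {}
        for table in entries.values():
            for pair, value in table.items():
                totals[pair] = totals.get(pair, 0.0) + value
        entries["total"] = totals

    regions = tuple(sorted(known))
    for region in sorted(phantom.source_regions):
        if (region, region) not in entries["total"]:
            raise ValidationError(
                f"{path}: self-dose entry ({region},{region}) is required for "
                f"every source region"
            )
    n_missing = sum(
        1
        for t in regions
        for s in regions
        if (t, s) not in entries["total"]
    )
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} cross-fire pair(s) absent; treated as S = 0",
            stacklevel=2,
        )
    return SValueMatrix(
        phantom_name=phantom.name,
        nuclide_name=nuclide_name,
        regions=regions,
        entries=entries,
    )


@dataclass(frozen=True)
class TissueWeightingTable:
    """Tissue (wT) and radiation (wR) weighting factors."""

    tissue: dict[str, float] = field(default_factory=dict)
    radiation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for tissue, w in self.tissue.items():
            if w < 0:
                raise ValidationError(f"wT for {tissue!r} must be >= 0")
        total = sum(self.tissue.values())
        if total > 1 + 1e-9:
            raise ValidationError(f"tissue weights sum to {total} > 1")
        if self.tissue and abs(total - 1.0) > 1e-9:
            warnings.warn(f"tissue weights sum to {total}, not 1", stacklevel=3)
        for rtype, w in self.radiation.items():
            if w < 1 - 1e-9:
                raise ValidationError(f"wR for {rtype!r} must be >= 1")


def load_weights(path) -> TissueWeightingTable:
    """Load ``weights.csv`` with columns ``kind (wT|wR), key, value``."""
    df = _read_csv(path, {"kind", "key", "value"})
    tissue, radiation = {}, {}
    for i, row in enumerate(df.itertuples(), start=2):
        kind = str(row.kind)
        if kind == "wT":
            tissue[str(row.key)] = float(row.value)
        elif kind == "wR":
            radiation[str(row.key)] = float(row.value)
        else:
            raise FormatError(f"{path} row {i}: kind must be 'wT' or 'wR', got {kind!r}")
    return TissueWeightingTable(tissue=tissue, radiation=radiation)
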